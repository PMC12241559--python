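"""Synthetic data generators: contact maps, fluorescence, expression.

The contact-map generator produces expected (noise-free) contact matrices for
a rearranged allele in its own coordinates, combining three multiplicative
ingredients standard in chromatin-contact modelling:

* a power-law distance decay ``(|i-j|+1)^(-alpha)`` of contact probability
  with genomic separation;
* CTCF-boundary insulation, attenuating contacts by a factor ``beta`` per
  intervening site (beta in (0, 1]);
* cell-state-specific loops, isotropic Gaussian bumps of amplitude ``kappa``
  and width ``w`` bins at anchor pairs. The active state stacks the promoter
  on its enhancers (Pen, PelB, PDE, RA4); the inactive state forms the
  repressive promoter-neighbour-gene (polycomb) contact instead.

Observed maps are independent Poisson draws on the upper triangle (optionally
negative-binomial for overdispersion), mirrored to keep symmetry. Bulk
populations are modelled as mixtures of active and inactive cells.

Fluorescence is a two-component log-normal mixture in log10 units with an
allele-independent "on" component — the shared ceiling of reporter abundance
in expressing cells. Expression tables follow a fixed-level / variable-
proportion model: each active cell transcribes the reporter at the same
level, so bulk expression scales linearly with the active-cell fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genome
from .config import PROPORTION_THETA
from .errors import ConfigurationError
from .genome import AlleleSpec, GenomicInterval, LandmarkMap, MappingError

__all__ = [
    "SimParams",
    "Loop",
    "CellStateTopology",
    "FluorescenceParams",
    "FluorescenceSample",
    "default_topologies",
    "expected_matrix",
    "sample_contact_map",
    "mix_populations",
    "proportion_response",
    "simulate_fluorescence",
    "simulate_expression",
]


@dataclass
class SimParams:
    """Contact-simulator parameters.

    total_reads is the expected total of the full (symmetric) matrix;
    decay_exponent alpha > 0; ctcf_insulation beta in (0, 1];
    loop_width_bins w > 0 is shared across loops.
    """

    region: GenomicInterval
    bin_size: int = 5_000
    decay_exponent: float = 1.0
    total_reads: float = 5e6
    ctcf_insulation: float = 0.7
    loop_width_bins: float = 2.0
    overdispersion: float | None = None  # NB dispersion (var = mu + a*mu^2)
    seed: int = 0

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ConfigurationError("decay exponent must be > 0")
        if not (0.0 < self.ctcf_insulation <= 1.0):
            raise ConfigurationError("ctcf_insulation must be in (0, 1]")
        if self.loop_width_bins <= 0:
            raise ConfigurationError("loop width must be > 0")
        if self.total_reads <= 0:
            raise ConfigurationError("total_reads must be > 0")
        if self.region.length % self.bin_size != 0:
            raise ConfigurationError("bin_size must divide the region length")

    @property
    def n_bins(self) -> int:
        return self.region.length // self.bin_size


@dataclass(frozen=True)
class Loop:
    """A cell-state loop between two named landmarks."""

    anchor_a: str
    anchor_b: str
    amplitude: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigurationError("loop amplitude must be >= 0")


@dataclass
class CellStateTopology:
    state: str  # "active" | "inactive"
    loops: list[Loop] = field(default_factory=list)


def default_topologies(pen_amplitude: float = 3.0,
                       enhancer_amplitude: float = 1.5,
                       repressive_amplitude: float = 2.5,
                       ) -> dict[str, CellStateTopology]:
    """Active enhancer-stack and inactive polycomb-contact topologies."""
    active = CellStateTopology("active", [
        Loop("P", "Pen", pen_amplitude),
        Loop("P", "PelB", enhancer_amplitude),
        Loop("P", "PDE", enhancer_amplitude),
        Loop("P", "RA4", enhancer_amplitude),
    ])
    inactive = CellStateTopology("inactive", [
        Loop("P", "N", repressive_amplitude),
    ])
    return {"active": active, "inactive": inactive}


def _landmark_bin_in_allele(name: str, allele: AlleleSpec,
                            landmarks: LandmarkMap) -> int:
    """Bin index of a landmark in allele coordinates.

    The mobilised Pen enhancer is located through its fragment centre so it
    follows the rearrangement; point landmarks map directly.
    """
    region = landmarks.region
    if name == "Pen":
        frag = genome.interval_in_allele(landmarks.pen_fragment, allele, region)
        pos = (frag.start + frag.end) // 2
    else:
        pos = genome.position_in_allele(landmarks.landmarks[name], allele, region)
    return (pos - region.start) // landmarks.bin_size


def expected_matrix(allele: AlleleSpec, state: CellStateTopology,
                    params: SimParams, landmarks: LandmarkMap) -> np.ndarray:
    """Expected contact matrix of one allele/state, in allele coordinates.

    E[i,j] = c * (|i-j|+1)^(-alpha) * beta^(#CTCF strictly between)
           * (1 + sum of loop bumps), normalised so the full matrix sums to
    ``total_reads``. Symmetric by construction.
    """
    region = landmarks.region
    B = params.bin_size
    n = genome._allele_length(allele, region) // B
    if n == 0:
        raise ConfigurationError("empty region")
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    E = (sep + 1.0) ** (-params.decay_exponent)

    # insulation: count CTCF sites with bin index strictly between i and j
    site_bins = []
    for site in landmarks.ctcf_sites:
        try:
            pos = genome.position_in_allele(site.pos, allele, region)
        except MappingError:
            continue
        site_bins.append((pos - region.start) // B)
    if site_bins and params.ctcf_insulation < 1.0:
        counts = np.bincount(np.array(site_bins), minlength=n)
        cum = np.concatenate([[0], np.cumsum(counts)])  # cum[b] = sites in bins < b
        lo = np.minimum(idx[:, None], idx[None, :])
        hi = np.maximum(idx[:, None], idx[None, :])
        # sites in bins (lo, hi) exclusive
        between = np.maximum(cum[hi] - cum[lo + 1], 0)
        E *= params.ctcf_insulation ** between

    if state.loops:
        w2 = 2.0 * params.loop_width_bins ** 2
        L = np.zeros((n, n))
        for loop in state.loops:
            a = _landmark_bin_in_allele(loop.anchor_a, allele, landmarks)
            b = _landmark_bin_in_allele(loop.anchor_b, allele, landmarks)
            bump = loop.amplitude * np.exp(
                -((idx[:, None] - a) ** 2 + (idx[None, :] - b) ** 2) / w2)
            L += bump + bump.T
        E *= 1.0 + L

    E *= params.total_reads / E.sum()
    return E


def sample_contact_map(expected: np.ndarray, seed: int,
                       overdispersion: float | None = None) -> np.ndarray:
    """Sample integer counts: independent Poisson on the upper triangle,
    mirrored to the lower. With ``overdispersion`` a, draws are
    negative-binomial with var = mu + a*mu^2 (gamma-Poisson mixture).
    """
    if np.any(expected < 0):
        raise ConfigurationError("expected matrix has negative entries")
    n = expected.shape[0]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n)
    mu = expected[iu]
    if overdispersion:
        shape = 1.0 / overdispersion
        mu = rng.gamma(shape, mu * overdispersion)
    counts = rng.poisson(mu)
    out = np.zeros((n, n), dtype=np.int64)
    out[iu] = counts
    out = out + np.triu(out, 1).T
    return out


def mix_populations(expected_active: np.ndarray, expected_inactive: np.ndarray,
                    p: float) -> np.ndarray:
    """Expected map of a bulk population with active-cell fraction ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"mixture fraction must be in [0, 1], got {p}")
    if expected_active.shape != expected_inactive.shape:
        raise ConfigurationError("population matrices are not congruent")
    return p * expected_active + (1.0 - p) * expected_inactive


def proportion_response(distance_bp: float, n_ctcf_between: int,
                        theta: tuple = PROPORTION_THETA) -> float:
    """Expected fraction of ectopically active cells for an allele geometry.

    logistic(theta0 - theta1*log10(distance) - theta2*n_ctcf): strictly
    decreasing in both the enhancer-promoter distance and the number of
    intervening CTCF sites. The functional form and coefficients are model
    calibration (see config module), not measured biology.
    """
    if distance_bp <= 0:
        raise ConfigurationError("distance must be > 0")
    if n_ctcf_between < 0:
        raise ConfigurationError("CTCF count must be >= 0")
    t0, t1, t2 = theta
    z = t0 - t1 * np.log10(distance_bp) - t2 * n_ctcf_between
    return float(1.0 / (1.0 + np.exp(-z)))


# ---------------------------------------------------------------------------
# Fluorescence

@dataclass
class FluorescenceParams:
    """Two-component log10-fluorescence mixture.

    The on-component location is the shared ceiling: identical across alleles
    by default, so expressing cells reach the same reporter abundance
    regardless of how many cells express.
    """

    n_cells: int = 20_000
    p_active: float = 0.0
    off_loc: float = 1.0
    off_scale: float = 0.25
    on_loc: float = 3.0
    on_scale: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be > 0")
        if not (0.0 <= self.p_active <= 1.0):
            raise ConfigurationError("p_active must be in [0, 1]")
        if self.off_scale <= 0 or self.on_scale <= 0:
            raise ConfigurationError("component scales must be > 0")


@dataclass
class FluorescenceSample:
    """Per-cell log10 fluorescence with a paired negative control."""

    values: np.ndarray
    label: str
    negative_control: np.ndarray

    def __post_init__(self):
        if len(self.values) < 1:
            raise ConfigurationError("empty fluorescence sample")
        if not (np.all(np.isfinite(self.values))
                and np.all(np.isfinite(self.negative_control))):
            raise ConfigurationError("non-finite fluorescence values")


def simulate_fluorescence(params: FluorescenceParams,
                          label: str = "",
                          n_control: int | None = None) -> FluorescenceSample:
    """Draw a fluorescence sample plus a paired off-component-only control."""
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    on = rng.random(n) < params.p_active
    values = np.where(
        on,
        rng.normal(params.on_loc, params.on_scale, n),
        rng.normal(params.off_loc, params.off_scale, n),
    )
    nc = n if n_control is None else n_control
    control = rng.normal(params.off_loc, params.off_scale, nc)
    return FluorescenceSample(values=values, label=label,
                              negative_control=control)


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(n_genes: int, hk_gene_count: int,
                        per_sample_depth_factors, active_level: float,
                        p_active_per_sample, seed: int = 0,
                        sample_ids=None, biological_cv: float = 0.5,
                        base_mean: float = 50.0):
    """Gene-by-sample counts with a stable housekeeping set and a reporter.

    Housekeeping genes have sample-independent expected expression (up to the
    depth factor); other genes get log-normal per-sample biological noise of
    coefficient ``biological_cv``. The reporter gene's expected bulk level is
    ``active_level * p_active`` — a fixed per-cell transcription level times
    the fraction of expressing cells — so equal-level alleles plateau at the
    same sorted-cell expression while bulk scales with the proportion.

    Returns an :class:`svlocus.expression.ExpressionTable` of Poisson counts.
    """
    from .expression import ExpressionTable  # local import; no cycle at import time
    import pandas as pd

    depth = np.asarray(per_sample_depth_factors, dtype=float)
    p_act = np.asarray(p_active_per_sample, dtype=float)
    if depth.shape != p_act.shape:
        raise ConfigurationError("depth factors and p_active lengths differ")
    if np.any(depth <= 0):
        raise ConfigurationError("depth factors must be > 0")
    if hk_gene_count > n_genes:
        raise ConfigurationError("hk_gene_count exceeds n_genes")
    n_samples = len(depth)
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]

    rng = np.random.default_rng(seed)
    gene_ids = ["reporter"] + [f"g{i}" for i in range(n_genes)]
    lengths = np.concatenate([[1_000.0],
                              rng.uniform(500, 10_000, n_genes).round()])
    is_hk = np.zeros(n_genes + 1, dtype=bool)
    is_hk[1:1 + hk_gene_count] = True

    base = rng.lognormal(np.log(base_mean), 1.0, n_genes)
    mu = np.empty((n_genes + 1, n_samples))
    mu[0] = active_level * p_act
    mu[1:] = base[:, None]
    if biological_cv > 0:
        sigma = np.sqrt(np.log1p(biological_cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2, sigma,
                              (n_genes - hk_gene_count, n_samples))
        mu[1 + hk_gene_count:] *= noise
    mu *= depth[None, :]
    counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return ExpressionTable(
        counts=counts_df,
        gene_lengths=pd.Series(lengths, index=gene_ids),
        is_housekeeping=pd.Series(is_hk, index=gene_ids),
    )
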