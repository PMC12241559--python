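"""Capture-HiC-style contact-map pipeline.

Region-restricted Knight-Ruiz balancing, distance-decay (per-subdiagonal)
scaling of map pairs, subtraction maps, percentile truncation, and
virtual-4C / anchor-pair quantification, with a tab-separated COO triplet
interchange format.

Conventions: a "subdiagonal" is the set of entries at one fixed genomic
separation d = |i-j|; scaling applies the same factor to the d-th super- and
subdiagonal so symmetry is preserved. Bins with zero raw coverage are masked
(rows and columns zeroed, excluded from balancing and quantification) —
balancing diverges on empty rows, so they are removed up front, as binned-map
pipelines conventionally do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import genome
from .errors import ConfigurationError, ConvergenceError, ParseError
from .genome import AlleleSpec, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "SubtractionMap",
    "Virtual4CProfile",
    "read_coo",
    "write_coo",
    "transform_to_reference",
    "kr_balance",
    "subdiagonal_scale_pair",
    "subtraction_map",
    "truncate_percentile",
    "virtual_4c",
    "quantify_pair",
    "anchor_for_landmark",
    "relative_difference_map",
    "locate_differential_extrema",
]

_SYMM_RTOL = 1e-9


@dataclass
class ContactMatrix:
    """A binned symmetric contact map over one genomic region.

    ``state`` tracks the processing stage: "raw" (integer counts),
    "balanced" (KR-normalised), or "subdiag_scaled" (distance-decay scaled
    against a partner map). ``mask`` lists excluded (zero-coverage) bins,
    whose rows and columns are all zero.
    """

    region: GenomicInterval
    bin_size: int
    values: np.ndarray
    state: str = "raw"
    mask: frozenset = frozenset()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.region.length // self.bin_size
        if self.values.shape != (n, n):
            raise ConfigurationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} bins for the region")
        if self.state not in ("raw", "balanced", "subdiag_scaled"):
            raise ConfigurationError(f"unknown matrix state {self.state!r}")
        scale = max(np.abs(self.values).max(), 1.0)
        if not np.allclose(self.values, self.values.T,
                           rtol=_SYMM_RTOL, atol=_SYMM_RTOL * scale):
            raise ConfigurationError("contact matrix is not symmetric")
        if np.any(self.values < 0):
            raise ConfigurationError("contact matrix has negative entries")
        self.mask = frozenset(int(i) for i in self.mask)
        for i in self.mask:
            if not (0 <= i < n):
                raise ConfigurationError(f"masked bin {i} out of range")

    @property
    def n_bins(self) -> int:
        return self.region.length // self.bin_size

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.mask)] = False
        return keep

    def bins_of(self, iv: GenomicInterval) -> np.ndarray:
        """Bin indices overlapping an interval (same coordinate system)."""
        if not (self.region.contains(iv.start) and self.region.contains(iv.end)):
            raise ConfigurationError(
                f"interval {iv.start}-{iv.end} outside the map region")
        lo = (iv.start - self.region.start) // self.bin_size
        hi = (iv.end - self.region.start) // self.bin_size
        return np.arange(lo, hi + 1)


@dataclass
class SubtractionMap:
    """Signed difference of two subdiagonal-scaled maps (A minus B)."""

    region: GenomicInterval
    bin_size: int
    values: np.ndarray
    provenance: tuple = ("A", "B")
    truncation_percentile: float | None = None
    mask: frozenset = frozenset()

    @property
    def n_bins(self) -> int:
        return self.region.length // self.bin_size


@dataclass
class Virtual4CProfile:
    """1-D contact profile of an anchor against every bin (NaN = masked)."""

    anchor: GenomicInterval
    values: np.ndarray
    source: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# COO TSV interchange

def write_coo(M: ContactMatrix, path) -> None:
    """Write upper-triangle nonzero entries as ``bin_i<TAB>bin_j<TAB>value``
    with a ``#key=value`` sidecar header. Floats use repr-round-trip format."""
    hdr = {
        "chrom": M.region.chrom,
        "start": M.region.start,
        "end": M.region.end,
        "assembly": M.region.assembly_tag,
        "bin_size": M.bin_size,
        "state": M.state,
        "mask": ",".join(str(i) for i in sorted(M.mask)),
    }
    hdr.update({k: v for k, v in M.metadata.items() if isinstance(v, (str, int, float))})
    with open(path, "w") as fh:
        for k, v in hdr.items():
            fh.write(f"#{k}={v}\n")
        iu = np.triu_indices(M.n_bins)
        vals = M.values[iu]
        nz = vals != 0
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            if float(v).is_integer():
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_coo(path) -> ContactMatrix:
    """Read the COO TSV format written by :func:`write_coo`.

    Lower-triangle entries are mirrored; duplicate (i, j) entries after
    canonicalising i <= j, out-of-range bins, and negative counts raise a
    :class:`ParseError` naming the line.
    """
    hdr: dict[str, str] = {}
    triplets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ParseError("malformed header line", lineno)
                k, v = line[1:].split("=", 1)
                hdr[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError("expected 3 tab-separated fields", lineno)
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise ParseError(str(e), lineno) from None
            triplets.append((lineno, i, j, v))
    for key in ("chrom", "start", "end", "bin_size"):
        if key not in hdr:
            raise ParseError(f"missing required header field #{key}=")
    region = GenomicInterval(hdr["chrom"], int(hdr["start"]), int(hdr["end"]),
                             hdr.get("assembly", "reference"))
    bin_size = int(hdr["bin_size"])
    n = region.length // bin_size
    values = np.zeros((n, n))
    seen: dict[tuple, tuple] = {}
    for lineno, i, j, v in triplets:
        if not (0 <= i < n and 0 <= j < n):
            raise ParseError(f"bin ({i}, {j}) out of range 0..{n - 1}", lineno)
        if v < 0:
            raise ParseError(f"negative count {v}", lineno)
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != v:
            raise ParseError(
                f"duplicate entry for bins {key} conflicts with earlier value",
                lineno)
        seen[key] = v
        values[key[0], key[1]] = v
        values[key[1], key[0]] = v
    mask = frozenset(int(x) for x in hdr.get("mask", "").split(",") if x != "")
    meta = {k: v for k, v in hdr.items()
            if k not in ("chrom", "start", "end", "assembly", "bin_size",
                         "state", "mask")}
    return ContactMatrix(region=region, bin_size=bin_size, values=values,
                         state=hdr.get("state", "raw"), mask=mask,
                         metadata=meta)


# ---------------------------------------------------------------------------
# Coordinate transform

def transform_to_reference(M: ContactMatrix, allele: AlleleSpec,
                           ref_region: GenomicInterval | None = None,
                           ) -> ContactMatrix:
    """Remap an allele-coordinate map onto the wildtype reference grid.

    All cross-allele comparisons are done in reference coordinates so every
    sample shares one bin axis. Counts of allele bins mapping to the same
    reference bin are accumulated; the total is conserved exactly.
    """
    if ref_region is None:
        # length-preserving alleles (inversions, relocations) share the
        # reference extent; net-deletion alleles must pass it explicitly
        ref_region = GenomicInterval(M.region.chrom, M.region.start,
                                     M.region.end, "reference")
    bmap = genome.allele_bin_map(allele, ref_region, M.bin_size)
    if len(bmap) != M.n_bins:
        raise ConfigurationError(
            f"allele {allele.name!r} implies {len(bmap)} bins but the map "
            f"has {M.n_bins}")
    n_ref = ref_region.length // M.bin_size
    out = genome.remap_matrix(M.values, bmap, n_ref)
    covered = np.zeros(n_ref, dtype=bool)
    covered[bmap] = True
    mask = {int(b) for b in np.nonzero(~covered)[0]}
    mask |= {int(bmap[i]) for i in M.mask}
    meta = dict(M.metadata, allele=allele.name)
    return ContactMatrix(
        region=GenomicInterval(ref_region.chrom, ref_region.start,
                               ref_region.end, "reference"),
        bin_size=M.bin_size, values=out, state=M.state,
        mask=frozenset(mask), metadata=meta)


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing

def _bnewt(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration for symmetric balancing.

    Returns x with diag(x) A diag(x) having unit row sums within ``tol``
    (max absolute row-sum deviation). Follows the conjugate-gradient inner
    iteration of the original algorithm.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = (0.5 * tol) ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    n_outer = 0
    total_inner = 0
    while np.max(np.abs(rk)) > tol:
        n_outer += 1
        if n_outer > max_iter or total_inner > 50 * max_iter:
            raise ConvergenceError(
                f"KR balancing did not converge: residual "
                f"{np.max(np.abs(rk)):.3e} after {n_outer} outer iterations",
                n_iter=n_outer, residual=float(np.max(np.abs(rk))))
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        total_inner += k + 1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), 0.5 * tol / max(res_norm, 1e-300))
    return x


def kr_balance(M: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000,
               min_row_sum: float | None = None, target: str | float = "mean",
               ) -> tuple[ContactMatrix, np.ndarray]:
    """Knight-Ruiz balance a raw map restricted to the captured region.

    Bins with raw row sum of zero (or below ``min_row_sum``) are masked and
    left untouched. Every unmasked row of the output sums to the target —
    the mean unmasked raw row sum by default, which keeps balanced values on
    a count-like scale so subtraction magnitudes stay comparable; pass
    ``target=1.0`` (or any number) for conventional unit row sums.

    Returns the balanced map and the full-length bias vector (NaN at masked
    bins), with ``balanced[i, j] = bias[i] * M[i, j] * bias[j]``.
    """
    if M.state != "raw":
        raise ConfigurationError(f"kr_balance expects a raw map, got {M.state!r}")
    values = M.values.astype(float)
    rowsum = values.sum(axis=1)
    cutoff = 0.0 if min_row_sum is None else min_row_sum
    keep = rowsum > max(cutoff - 1e-12, 0.0) if cutoff > 0 else rowsum > 0
    keep[list(M.mask)] = False
    if not np.any(keep):
        raise ConfigurationError("matrix is entirely zero; nothing to balance")
    sub = values[np.ix_(keep, keep)]
    if np.any(sub.sum(axis=1) <= 0):
        keep_idx = np.nonzero(keep)[0]
        dead = keep_idx[sub.sum(axis=1) <= 0]
        keep[dead] = False
        sub = values[np.ix_(keep, keep)]
    T = float(target) if not isinstance(target, str) else \
        float(values[np.ix_(keep, keep)].sum(axis=1).mean())
    # diag(x) (sub/T) diag(x) has unit row sums, so diag(x) sub diag(x)
    # has row sums exactly T: the bias vector is x itself.
    x = _bnewt(sub / T, tol=tol, max_iter=max_iter)
    bias_sub = x
    balanced_sub = (bias_sub[:, None] * sub) * bias_sub[None, :]
    n = M.n_bins
    out = np.zeros((n, n))
    out[np.ix_(keep, keep)] = balanced_sub
    bias = np.full(n, np.nan)
    bias[keep] = bias_sub
    mask = frozenset(int(i) for i in np.nonzero(~keep)[0])
    meta = dict(M.metadata, kr_tol=tol, kr_target=T)
    return (ContactMatrix(region=M.region, bin_size=M.bin_size, values=out,
                          state="balanced", mask=mask, metadata=meta),
            bias)


# ---------------------------------------------------------------------------
# Distance-decay scaling and subtraction

def _diag_sums(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    sums = np.empty(n)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        k = keep[:n - d] & keep[d:]
        sums[d] = diag[k].sum()
    return sums


def subdiagonal_scale_pair(A: ContactMatrix, B: ContactMatrix,
                           include_diagonal: bool = True,
                           ) -> tuple[ContactMatrix, ContactMatrix]:
    """Scale each subdiagonal of two balanced maps to their common average.

    For separation d, each map's d-th subdiagonal vector is divided by its
    own sum and multiplied by the mean of the two sums, so after scaling both
    maps put identical total signal at every genomic separation — removing
    the distance-decay difference before subtraction. If one map's diagonal
    sum is zero while the other's is not, the zero side stays zero and the
    non-zero side is scaled to the average (logged); two zero sums leave both
    untouched. Masked bins are excluded from the sums.
    """
    for name, m in (("A", A), ("B", B)):
        # already-scaled pairs are accepted: re-scaling is then the identity
        if m.state not in ("balanced", "subdiag_scaled"):
            raise ConfigurationError(
                f"subdiagonal scaling expects balanced maps; {name} is "
                f"{m.state!r}")
    if A.n_bins != B.n_bins or A.bin_size != B.bin_size:
        raise ConfigurationError("maps are not congruent")
    n = A.n_bins
    # harmonise masks: a bin unusable in either map is excluded from both,
    # otherwise per-diagonal sums are taken over different entry sets and
    # the subtraction map loses its zero-sum property
    union_mask = A.mask | B.mask
    keep = np.ones(n, dtype=bool)
    keep[list(union_mask)] = False
    valsA = A.values.copy()
    valsB = B.values.copy()
    valsA[~keep, :] = 0.0
    valsA[:, ~keep] = 0.0
    valsB[~keep, :] = 0.0
    valsB[:, ~keep] = 0.0
    sA = _diag_sums(valsA, keep)
    sB = _diag_sums(valsB, keep)
    avg = 0.5 * (sA + sB)
    fA = np.ones(n)
    fB = np.ones(n)
    both = (sA > 0) & (sB > 0)
    fA[both] = avg[both] / sA[both]
    fB[both] = avg[both] / sB[both]
    onlyA = (sA > 0) & (sB == 0)
    onlyB = (sB > 0) & (sA == 0)
    fA[onlyA] = avg[onlyA] / sA[onlyA]
    fB[onlyB] = avg[onlyB] / sB[onlyB]
    if np.any(onlyA) or np.any(onlyB):
        logger.warning(
            "subdiagonal scaling: %d diagonals have signal in only one map",
            int(np.sum(onlyA) + np.sum(onlyB)))
    if not include_diagonal:
        fA[0] = 1.0
        fB[0] = 1.0
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    outA = valsA * fA[sep]
    outB = valsB * fB[sep]
    mkA = replace(A, values=outA, state="subdiag_scaled", mask=union_mask,
                  metadata=dict(A.metadata, scaled_with=B.metadata.get(
                      "population", "partner")))
    mkB = replace(B, values=outB, state="subdiag_scaled", mask=union_mask,
                  metadata=dict(B.metadata, scaled_with=A.metadata.get(
                      "population", "partner")))
    return mkA, mkB


def subtraction_map(A: ContactMatrix, B: ContactMatrix) -> SubtractionMap:
    """Subtract two subdiagonal-scaled maps (A minus B).

    Positive values mark contacts preferential in A; every subdiagonal sums
    to zero because the inputs were scaled to equal per-diagonal totals, and
    swapping the inputs negates the map exactly.
    """
    for name, m in (("A", A), ("B", B)):
        if m.state != "subdiag_scaled":
            raise ConfigurationError(
                f"subtraction expects subdiag_scaled maps; {name} is "
                f"{m.state!r}")
    if A.n_bins != B.n_bins or A.bin_size != B.bin_size:
        raise ConfigurationError("maps are not congruent")
    prov = (A.metadata.get("population", "A"), B.metadata.get("population", "B"))
    return SubtractionMap(region=A.region, bin_size=A.bin_size,
                          values=A.values - B.values, provenance=prov,
                          mask=A.mask | B.mask)


def truncate_percentile(M, q: float = 99.0):
    """Clip extreme values at the q-th percentile (visualisation convention).

    For a ContactMatrix the percentile is computed over the unmasked
    upper-triangle values (linear-interpolation percentile) and values above
    it are set to it. For a SubtractionMap the clip is applied symmetrically
    by magnitude: values beyond +/- the q-th percentile of |values| are
    clipped, preserving sign. Returns a new object; q = 100 is the identity.
    """
    if not (0.0 < q <= 100.0):
        raise ConfigurationError("percentile must be in (0, 100]")
    if isinstance(M, SubtractionMap):
        keep = np.ones(M.n_bins, dtype=bool)
        keep[list(M.mask)] = False
        iu = np.triu_indices(M.n_bins)
        sel = keep[iu[0]] & keep[iu[1]]
        mags = np.abs(M.values[iu][sel])
        cut = np.percentile(mags, q)
        return replace(M, values=np.clip(M.values, -cut, cut),
                       truncation_percentile=q)
    keep = M.unmasked()
    iu = np.triu_indices(M.n_bins)
    sel = keep[iu[0]] & keep[iu[1]]
    cut = np.percentile(M.values[iu][sel], q)
    out = np.minimum(M.values, cut)
    return replace(M, values=out,
                   metadata=dict(M.metadata, truncation_percentile=q))


# ---------------------------------------------------------------------------
# Quantification

def anchor_for_landmark(landmarks, name: str,
                        flank_bins: int = 1) -> GenomicInterval:
    """Anchor window for a named landmark: its bin plus ``flank_bins`` on
    each side (15 kb at default 5-kb bins), the dot size quantified."""
    b = landmarks.bin_of(landmarks.landmarks[name])
    lo = max(b - flank_bins, 0)
    hi = min(b + flank_bins, landmarks.n_bins - 1)
    r = landmarks.region
    return GenomicInterval(r.chrom, r.start + lo * landmarks.bin_size,
                           r.start + (hi + 1) * landmarks.bin_size - 1)


def virtual_4c(M: ContactMatrix, anchor: GenomicInterval) -> Virtual4CProfile:
    """Mean contact of the anchor bins against every bin of the region.

    Masked bins (as anchor rows or as profile columns) are reported as NaN,
    not zero.
    """
    rows = M.bins_of(anchor)
    keep = M.unmasked()
    rows = rows[keep[rows]]
    n = M.n_bins
    if len(rows) == 0:
        values = np.full(n, np.nan)
    else:
        values = M.values[rows].mean(axis=0)
        values[~keep] = np.nan
    return Virtual4CProfile(anchor=anchor, values=values,
                            source=dict(M.metadata, state=M.state))


def quantify_pair(M: ContactMatrix, anchor_a: GenomicInterval,
                  anchor_b: GenomicInterval) -> float:
    """Mean contact over the rectangle anchor_a x anchor_b.

    Masked bins are excluded; an entirely masked rectangle yields NaN
    (missing), never zero. Symmetric in the two anchors because the map is.
    """
    rows = M.bins_of(anchor_a)
    cols = M.bins_of(anchor_b)
    keep = M.unmasked()
    rows = rows[keep[rows]]
    cols = cols[keep[cols]]
    if len(rows) == 0 or len(cols) == 0:
        return float("nan")
    return float(M.values[np.ix_(rows, cols)].mean())


# ---------------------------------------------------------------------------
# Differential-signal localisation

def relative_difference_map(S: SubtractionMap, A: ContactMatrix,
                            B: ContactMatrix) -> np.ndarray:
    """Subtraction map expressed relative to the local distance-decay level.

    Each entry of S is divided by the per-diagonal mean of the averaged pair
    (A + B) / 2, giving a fold-like differential signal comparable across
    genomic separations. Diagonals with zero mean map to zero.
    """
    n = S.n_bins
    keep = np.ones(n, dtype=bool)
    keep[list(S.mask)] = False
    avg = 0.5 * (A.values + B.values)
    means = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(avg, offset=d)
        k = keep[:n - d] & keep[d:]
        if k.any():
            means[d] = diag[k].mean()
    rows, cols = np.indices((n, n))
    sep = np.abs(rows - cols)
    denom = means[sep]
    out = np.zeros_like(S.values)
    nz = denom > 0
    out[nz] = S.values[nz] / denom[nz]
    return out


def locate_differential_extrema(S: SubtractionMap, A: ContactMatrix,
                                B: ContactMatrix, min_sep: int = 5,
                                max_sep: int = 200,
                                smooth_sigma: float = 2.0,
                                ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the strongest positive and negative differential signals.

    The detection statistic is a per-separation z-score: the relative
    difference map is smoothed with an isotropic Gaussian matched to the
    loop width (a matched filter), then each subdiagonal is standardised by
    its own robust noise level (median absolute deviation), because the
    sampling noise of the relative difference grows with genomic separation
    as the expected contact level decays. The search is restricted to
    separations in [min_sep, max_sep] bins: below, focal signals are not
    separable from the main diagonal; above, even the standardised statistic
    is estimated from too few informative pixels. Returns the pixel
    coordinates ((i+, j+), (i-, j-)), each with i <= j.
    """
    from scipy.ndimage import gaussian_filter

    rel = relative_difference_map(S, A, B)
    if smooth_sigma > 0:
        rel = gaussian_filter(rel, smooth_sigma, mode="nearest")
    n = S.n_bins
    # robust per-diagonal standardisation (MAD); the floor avoids blow-ups
    # on nearly noise-free diagonals
    scale = np.ones(n)
    for d in range(n):
        diag = np.diagonal(rel, offset=d)
        if diag.size:
            mad = np.median(np.abs(diag - np.median(diag)))
            scale[d] = 1.4826 * mad
    floor = max(np.median(scale[min_sep:max_sep + 1]) * 1e-3, 1e-12)
    scale = np.maximum(scale, floor)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    z = rel / scale[sep]
    valid = (sep >= min_sep) & (sep <= max_sep)
    masked = np.zeros(n, dtype=bool)
    masked[list(S.mask)] = True
    valid &= ~masked[:, None] & ~masked[None, :]
    work = np.where(valid, z, 0.0)
    imax = np.unravel_index(np.argmax(work), work.shape)
    imin = np.unravel_index(np.argmin(work), work.shape)
    pos = (int(min(imax)), int(max(imax)))
    neg = (int(min(imin)), int(max(imin)))
    return pos, neg
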