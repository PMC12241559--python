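"""End-to-end scenario runs: simulate -> liftover -> balance -> diffmap ->
quantify -> proportions -> expression, from a single config.

For every allele preset the scenario simulates sorted reporter-positive and
reporter-negative cell populations (active/inactive topology mixtures at the
configured sorting purity), maps them onto the reference coordinate grid,
KR-balances, builds the distance-normalised subtraction map, quantifies the
promoter-Pen contact, estimates the positive-cell proportion from simulated
fluorescence, and measures normalised reporter expression in sorted-positive
samples. Results are collected in a cross-allele summary table; all outputs
carry the config hash and seed, and reruns with identical config are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts, cytometry, expression, genome, simulate
from .config import RunConfig, config_hash
from .errors import SVLocusError

logger = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "AlleleResult", "run_scenario"]

_SUMMARY_COLUMNS = [
    "allele", "distance_bp", "n_ctcf", "p_model", "p_hat",
    "pen_contact", "ceiling_log10", "reporter_fpkm_norm",
]


@dataclass
class AlleleResult:
    allele: str
    balanced_pos: contacts.ContactMatrix
    balanced_neg: contacts.ContactMatrix
    subtraction: contacts.SubtractionMap
    gate: cytometry.GateResult
    ceiling: float | None
    pen_contact: float
    p_model: float
    distance_bp: int
    n_ctcf: int


@dataclass
class ScenarioResult:
    summary: pd.DataFrame
    alleles: dict = field(default_factory=dict)
    expression_table: expression.ExpressionTable | None = None
    config: RunConfig | None = None
    output_dir: Path | None = None


def _stage(name: str):
    """Decorator-free stage guard: annotate failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SVLocusError):
                logger.error("stage %s failed: %s", name, exc)
                exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            return False
    return _Ctx()


def run_scenario(config: RunConfig, output_dir=None) -> ScenarioResult:
    """Run the full multi-allele scenario described by ``config``."""
    config.validate()
    chash = config_hash(config)
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    with _stage("setup"):
        landmarks = genome.build_reference_locus(
            {"region": tuple(config.region), "bin_size": config.bin_size})
        presets = genome.allele_presets(landmarks)
        topo = simulate.default_topologies(
            pen_amplitude=config.pen_loop_amplitude,
            enhancer_amplitude=config.enhancer_loop_amplitude,
            repressive_amplitude=config.repressive_loop_amplitude)
        params = simulate.SimParams(
            region=landmarks.region, bin_size=config.bin_size,
            decay_exponent=config.decay_exponent,
            total_reads=config.total_reads,
            ctcf_insulation=config.ctcf_insulation,
            loop_width_bins=config.loop_width_bins, seed=config.seed)
        anchor_p = contacts.anchor_for_landmark(
            landmarks, "P", config.anchor_flank_bins)
        anchor_pen = contacts.anchor_for_landmark(
            landmarks, "Pen", config.anchor_flank_bins)

    results: dict[str, AlleleResult] = {}
    rows = []
    allele_names = list(config.alleles)
    for name in allele_names:
        if name not in presets:
            raise SVLocusError(f"[stage setup] unknown allele preset {name!r}")
        allele = presets[name]
        seed_maps = int(rng.integers(2 ** 31))
        seed_fluo = int(rng.integers(2 ** 31))

        with _stage(f"simulate:{name}"):
            E_act = simulate.expected_matrix(allele, topo["active"], params,
                                             landmarks)
            E_ina = simulate.expected_matrix(allele, topo["inactive"], params,
                                             landmarks)
            p_model = simulate.proportion_response(
                genome.pen_promoter_distance(allele, landmarks),
                genome.ctcf_between_pen_and_promoter(allele, landmarks),
                theta=config.proportion_theta)
            E_pos = simulate.mix_populations(E_act, E_ina, config.sort_purity)
            E_neg = simulate.mix_populations(E_act, E_ina,
                                             1.0 - config.sort_purity)
            raw_pos = simulate.sample_contact_map(E_pos, seed_maps)
            raw_neg = simulate.sample_contact_map(E_neg, seed_maps + 1)

        with _stage(f"balance:{name}"):
            region_allele = genome.GenomicInterval(
                landmarks.region.chrom, landmarks.region.start,
                landmarks.region.end, assembly_tag=name)
            m_pos = contacts.ContactMatrix(
                region=region_allele, bin_size=config.bin_size,
                values=raw_pos, metadata={"allele": name, "population": "pos"})
            m_neg = contacts.ContactMatrix(
                region=region_allele, bin_size=config.bin_size,
                values=raw_neg, metadata={"allele": name, "population": "neg"})
            ref_pos = contacts.transform_to_reference(m_pos, allele,
                                                      landmarks.region)
            ref_neg = contacts.transform_to_reference(m_neg, allele,
                                                      landmarks.region)
            bal_pos, _ = contacts.kr_balance(ref_pos, tol=config.kr_tol,
                                             max_iter=config.kr_max_iter)
            bal_neg, _ = contacts.kr_balance(ref_neg, tol=config.kr_tol,
                                             max_iter=config.kr_max_iter)

        with _stage(f"diffmap:{name}"):
            sc_pos, sc_neg = contacts.subdiagonal_scale_pair(bal_pos, bal_neg)
            diff = contacts.subtraction_map(sc_pos, sc_neg)
            diff = contacts.truncate_percentile(diff, config.truncate_q)

        with _stage(f"quantify:{name}"):
            pen_contact = contacts.quantify_pair(bal_pos, anchor_p, anchor_pen)

        with _stage(f"proportions:{name}"):
            fluo = simulate.simulate_fluorescence(
                simulate.FluorescenceParams(
                    n_cells=config.n_cells, p_active=p_model,
                    off_loc=config.off_loc, off_scale=config.off_scale,
                    on_loc=config.on_loc, on_scale=config.on_scale,
                    seed=seed_fluo),
                label=name)
            thr = cytometry.gate_threshold(fluo.negative_control,
                                           config.control_quantile)
            gate = cytometry.proportion_positive(fluo.values, thr,
                                                 config.control_quantile)
            ceiling = cytometry.ceiling_statistic(fluo.values, thr)

        results[name] = AlleleResult(
            allele=name, balanced_pos=bal_pos, balanced_neg=bal_neg,
            subtraction=diff, gate=gate, ceiling=ceiling,
            pen_contact=pen_contact, p_model=p_model,
            distance_bp=genome.pen_promoter_distance(allele, landmarks),
            n_ctcf=genome.ctcf_between_pen_and_promoter(allele, landmarks))

    with _stage("expression"):
        seed_expr = int(rng.integers(2 ** 31))
        n_rep = config.n_replicates
        sample_ids = []
        p_active = []
        for name in allele_names:
            for r in range(n_rep):
                sample_ids.append(f"{name}_pos_{r}")
                p_active.append(1.0)  # sorted-positive cells: fixed level
        depth_rng = np.random.default_rng(seed_expr)
        depth = depth_rng.lognormal(0.0, 0.15, len(sample_ids))
        table = simulate.simulate_expression(
            n_genes=config.n_genes, hk_gene_count=config.hk_gene_count,
            per_sample_depth_factors=depth, active_level=config.active_level,
            p_active_per_sample=p_active, seed=seed_expr,
            sample_ids=sample_ids)
        table.groups = pd.Series(
            [s.rsplit("_", 2)[0] for s in sample_ids], index=sample_ids)
        expression.housekeeping_coefficients(table)

    for name in allele_names:
        res = results[name]
        cols = table.groups.index[table.groups == name]
        reporter = float(table.normalized_fpkm.loc["reporter", cols].mean())
        rows.append({
            "allele": name,
            "distance_bp": res.distance_bp,
            "n_ctcf": res.n_ctcf,
            "p_model": res.p_model,
            "p_hat": res.gate.positive_fraction,
            "pen_contact": res.pen_contact,
            "ceiling_log10": np.nan if res.ceiling is None else res.ceiling,
            "reporter_fpkm_norm": reporter,
        })
    summary = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)

    with _stage("write"):
        header = f"#config_hash={chash}\n#seed={config.seed}\n"
        spath = outdir / "summary.tsv"
        with open(spath, "w") as fh:
            fh.write(header)
            summary.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        for name, res in results.items():
            res.balanced_pos.metadata["config_hash"] = chash
            res.balanced_pos.metadata["seed"] = config.seed
            res.balanced_neg.metadata["config_hash"] = chash
            res.balanced_neg.metadata["seed"] = config.seed
            contacts.write_coo(res.balanced_pos,
                               outdir / f"{name}_pos_balanced.tsv")
            contacts.write_coo(res.balanced_neg,
                               outdir / f"{name}_neg_balanced.tsv")
            _write_subtraction(res.subtraction, outdir / f"{name}_diff.tsv",
                               chash, config.seed)
        if config.make_plots:
            _plot_maps(results, outdir, chash)

    logger.info("scenario complete: %d alleles, config %s", len(results), chash)
    return ScenarioResult(summary=summary, alleles=results,
                          expression_table=table, config=config,
                          output_dir=outdir)


def _write_subtraction(S: contacts.SubtractionMap, path, chash, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"#config_hash={chash}\n#seed={seed}\n")
        fh.write(f"#provenance={S.provenance[0]}-minus-{S.provenance[1]}\n")
        if S.truncation_percentile is not None:
            fh.write(f"#truncation_percentile={S.truncation_percentile}\n")
        iu = np.triu_indices(S.n_bins)
        vals = S.values[iu]
        nz = vals != 0
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def _plot_maps(results: dict, outdir: Path, chash: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # shared colour bound across subtraction maps ("homogenised" scales)
    bound = max(np.abs(r.subtraction.values).max() for r in results.values())
    for name, res in results.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(res.subtraction.values, cmap="seismic",
                       vmin=-bound, vmax=bound)
        ax.set_title(f"{name} pos-minus-neg (scale ±{bound:.3g}, {chash})")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(outdir / f"{name}_diff.png", dpi=120)
        plt.close(fig)


def anchors_match(pixel: tuple, anchor_pairs: list, tol_bins: int = 2) -> bool:
    """Whether a pixel lies within ``tol_bins`` of any planted anchor pair."""
    i, j = pixel
    for a, b in anchor_pairs:
        lo, hi = min(a, b), max(a, b)
        if abs(i - lo) <= tol_bins and abs(j - hi) <= tol_bins:
            return True
    return False
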