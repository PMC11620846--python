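"""End-to-end analysis pipeline: records in, report CSVs out.

Stages run in a fixed order — importance values, dominant-species
screening, niche breadth/overlap, association tests, phylogenetic
structure, then environmental ordination — and each stage's outputs are
written as plain CSV under the configured output directory, together with
a markdown summary and a run log.  All stochastic stages derive their seed
from the pipeline seed plus a fixed per-stage offset, so a stage re-run in
isolation reproduces its in-pipeline result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, importance, niche, phylo
from .environment import pca_rank, rda_forward_select
from .io import (PhyloDistances, environment_frame, read_environment,
                 read_newick_distances, read_records)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("coexistkit")

# Per-stage seed offsets (stage-level reproducibility).
_SEED_NRI = 101
_SEED_RDA = 202

SOIL_VARS = ["pH", "t_k", "a_k", "t_p", "a_p", "t_n", "a_n", "som", "salt"]


@dataclass
class PipelineConfig:
    records: str
    env: str | None = None
    tree: str | None = None
    outdir: str = "coexistkit_out"
    dominant_threshold: float = 1.0
    gradients: list[str] = field(default_factory=list)  # env columns, 'table6' schemes
    n_rand: int = 999
    n_perm: int = 499
    alpha: float = 0.05
    seed: int = 0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every applicable stage; returns the in-memory report bundle."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("seed=%d records=%s", cfg.seed, cfg.records)
    bundle: dict = {"seed": cfg.seed}
    try:
        records = _stage("read_records")(read_records)(cfg.records)
        if not records:
            raise PipelineError("importance", ValueError("no records in input"))
        iv = _stage("importance")(importance.compute_importance)(records)
        iv.per_plot.to_csv(out / "importance.csv", index=False)
        iv.mean_iv.to_csv(out / "mean_iv.csv")
        dominant = _stage("screen")(importance.screen_dominant)(
            iv, cfg.dominant_threshold)
        pd.Series(dominant, name="species").to_csv(out / "dominant.csv", index=False)
        bundle["importance"] = iv
        bundle["dominant"] = dominant
        if len(dominant) < 2:
            raise PipelineError(
                "screen", ValueError("fewer than 2 dominant species"))

        iv_dom = iv.iv_matrix.loc[dominant]

        # Niche at the overall level: the plots themselves are the states.
        profiles = _stage("niche")(niche.niche_profiles)(iv_dom)
        breadth = profiles.apply(niche.shannon_breadth, axis=1)
        breadth.name = "bs_overall"
        omat = niche.overlap_matrix(profiles)
        osum = niche.overlap_summary(omat)
        breadth.to_csv(out / "breadth_overall.csv")
        omat.to_csv(out / "overlap_overall.csv")
        bundle["breadth"] = breadth
        bundle["overlap"] = omat
        bundle["overlap_summary"] = osum

        env_frame = None
        if cfg.env:
            envs = _stage("read_environment")(read_environment)(cfg.env)
            env_frame = environment_frame(envs)
            for var in cfg.gradients:
                scheme = niche.table6_scheme(var) if var in ("pH", "t_k", "a_k") \
                    else None
                if scheme is None:
                    raise PipelineError(
                        "niche", ValueError(f"no level scheme for {var!r}"))
                _, level_iv = _stage("niche")(niche.bin_gradient)(
                    iv_dom, env_frame[var], scheme)
                gp = niche.niche_profiles(level_iv)
                gb = gp.apply(niche.shannon_breadth, axis=1)
                gb.name = f"bs_{var}"
                gb.to_csv(out / f"breadth_{var}.csv")
                bundle[f"breadth_{var}"] = gb

        presence = _stage("association")(association.to_presence)(iv_dom)
        vr = association.variance_ratio_test(presence, cfg.alpha)
        pairs, chi2_summary = association.pairwise_association(presence)
        abundance = _records_abundance(records, dominant)
        corr, corr_summaries = association.correlation_tests(abundance)
        _pairs_frame(pairs).to_csv(out / "chi2_pairs.csv", index=False)
        corr.to_csv(out / "correlations.csv", index=False)
        _semi_matrix(corr, dominant).to_csv(out / "correlation_semimatrix.csv")
        bundle["variance_ratio"] = vr
        bundle["chi2_summary"] = chi2_summary
        bundle["correlation_summaries"] = corr_summaries

        if cfg.tree:
            dist = _stage("nri")(read_newick_distances)(cfg.tree)
            common = [s for s in dominant if s in dist.taxa]
            results, nri_summary = _stage("nri")(phylo.nri)(
                presence.loc[common], dist, n_rand=cfg.n_rand,
                seed=cfg.seed + _SEED_NRI)
            _nri_frame(results).to_csv(out / "nri.csv", index=False)
            bundle["nri_summary"] = nri_summary

        if env_frame is not None:
            soil_cols = [c for c in SOIL_VARS if c in env_frame.columns]
            if len(soil_cols) >= 2:
                pca = _stage("pca")(pca_rank)(env_frame, soil_cols)
                _pca_frame(pca).to_csv(out / "pca.csv")
                bundle["pca"] = pca
            candidates = env_frame.select_dtypes(include=[np.number])
            candidates = candidates.loc[:, candidates.std(ddof=1) > 0]
            rda = _stage("rda")(rda_forward_select)(
                iv_dom, candidates, n_perm=cfg.n_perm, alpha=cfg.alpha,
                seed=cfg.seed + _SEED_RDA)
            rda.steps.to_csv(out / "rda_selection.csv", index=False)
            bundle["rda"] = rda
            if rda.species_scores is not None and len(rda.species_scores) >= 3:
                groups = association.assign_species_groups(rda.species_scores)
                groups.to_csv(out / "species_groups.csv",
                              header=["group (heuristic clustering)"])
                bundle["groups"] = groups

        _write_summary(out / "summary.md", cfg, bundle)
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()


def _records_abundance(records, species) -> pd.DataFrame:
    df = pd.DataFrame({
        "plot": [r.plot_id for r in records],
        "species": [r.species for r in records],
        "abundance": [r.abundance for r in records],
    })
    mat = df.pivot_table(index="species", columns="plot", values="abundance",
                         aggfunc="sum", fill_value=0)
    return mat.reindex(species, fill_value=0)


def _pairs_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame([{
        "species_i": p.species_i, "species_k": p.species_k,
        "a": p.a, "b": p.b, "c": p.c, "d": p.d,
        "chi2": p.chi2, "sign": p.sign, "significance": p.significance,
    } for p in pairs])


def _nri_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "plot": r.plot_id, "n_taxa": r.n_taxa, "mpd_obs": r.mpd_obs,
        "null_mean": r.null_mean, "null_sd": r.null_sd, "nri": r.nri,
        "degenerate": r.degenerate, "n_rand": r.n_rand, "seed": r.seed,
    } for r in results])


def _pca_frame(pca) -> pd.DataFrame:
    comps = [f"PC{i + 1}" for i in range(len(pca.eigenvalues))]
    return pd.DataFrame(
        [pca.eigenvalues, pca.proportion_explained, pca.cumulative_proportion],
        index=["eigenvalue", "proportion_explained", "cumulative_proportion"],
        columns=comps)


def _semi_matrix(corr: pd.DataFrame, species: list[str]) -> pd.DataFrame:
    """Square CSV: Spearman above the diagonal, Pearson below, stars kept."""
    m = pd.DataFrame("", index=species, columns=species, dtype=object)
    for _, row in corr.iterrows():
        i, k = row["species_i"], row["species_k"]
        m.loc[i, k] = f"{row['r_spearman']:.2f}{row['stars_spearman']}"
        m.loc[k, i] = f"{row['r_pearson']:.2f}{row['stars_pearson']}"
    return m


def _write_summary(path, cfg: PipelineConfig, b: dict) -> None:
    lines = [
        "# Community analysis summary",
        f"seed: {cfg.seed}",
        "",
        f"Dominant species (mean IV > {cfg.dominant_threshold}%): "
        f"{len(b['dominant'])}",
    ]
    if "variance_ratio" in b:
        vr = b["variance_ratio"]
        lines += [
            "",
            f"Overall association: VR = {vr.vr:.3f}, W = {vr.w:.2f}, "
            f"bounds ({vr.lower:.2f}, {vr.upper:.2f}) -> {vr.verdict}",
        ]
    if "overlap_summary" in b:
        s = b["overlap_summary"]
        lines += [
            "",
            f"Niche overlap: {s['n_pairs']} pairs, {s['n_ge']} with O >= 0.5 "
            f"({s['pct_ge']:.2f}%), mean {s['mean']:.2f}, "
            f"range {s['min']:.2f}-{s['max']:.2f}",
        ]
    if "chi2_summary" in b:
        s = b["chi2_summary"]
        lines += [
            "",
            f"Chi-square pairs: {s['n_positive']} positive / "
            f"{s['n_negative']} negative (ratio "
            f"{s['pos_neg_ratio']:.2f}), significance rate "
            f"{s['significance_rate_pct']:.2f}%",
        ]
    if "nri_summary" in b:
        s = b["nri_summary"]
        lines += [
            "",
            f"NRI: {s['n_positive']} positive : {s['n_negative']} negative "
            f"(mean {s['mean_nri']:.3f})",
        ]
    if "rda" in b:
        sel = b["rda"].selected
        lines += [
            "",
            f"RDA forward selection: {', '.join(sel) if sel else 'none'} "
            f"(explained {b['rda'].total_explained:.3f})",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
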