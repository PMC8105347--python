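"""End-to-end orchestration: simulate/load -> extract -> align -> EFA ->
statistics -> classification benchmark -> assignment of unknowns.

Every run is driven by a :class:`RunConfig` with a mandatory RNG seed; each
stage draws its randomness from a named substream spawned from that seed,
so single stages are reproducible independently of the others.  All
tabular outputs are plain CSV, the tree is Newick, and ``summary.json``
collects every headline statistic of the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, efa, imaging, morphostats, synthetic

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("seedmorph")

_STAGES = ("simulate", "extract", "efa", "stats", "classify", "assign")


@dataclass
class RunConfig:
    """All protocol constants of one analysis run.

    The defaults encode the reference protocol: 360-point resampling,
    harmonics retained at 95% cumulative power, classes balanced to 30
    specimens, 1000 benchmark permutations and 100 assignment permutations.
    """

    rng_seed: int
    outdir: str = "seedmorph_run"
    masks_dir: str | None = None
    landmarks_path: str | None = None
    descriptors_path: str | None = None
    simulate: bool = True
    separation: float = 1.0
    seeds_per_taxon: int | None = None   # override model n_seeds (scaling)
    n_unknowns: int = 33
    include_extra_accessions: bool = True
    include_repeatability: bool = True
    px_per_mm: float = 100.0
    rotation_sd: float = 0.02
    outline_jitter_sd: float = 0.0008
    landmark_jitter_sd: float = 0.001
    k_points: int = 360
    harmonic_threshold: float = 0.95
    harmonic_drop_first: bool = True
    max_harmonics: int = 8
    n_per_class: int = 30
    n_perm_benchmark: int = 1000
    n_perm_assign: int = 100
    feature_sets: tuple = ("cells", "size", "shape", "size+cells", "all")

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        for name in ("k_points", "max_harmonics", "n_per_class",
                     "n_perm_benchmark", "n_perm_assign", "n_unknowns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.harmonic_threshold <= 1:
            raise ValueError("harmonic_threshold must lie in (0, 1]")
        self.feature_sets = tuple(self.feature_sets)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage RNG seed from the run seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.rng_seed).spawn(len(_STAGES))[idx]
        return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig):
    """Generate the reference + unknown populations and repeatability sets."""
    seed = cfg.stage_seed("simulate")
    noise = synthetic.NoiseSpec(
        rotation_sd=cfg.rotation_sd,
        outline_jitter_sd=cfg.outline_jitter_sd,
        landmark_jitter_sd=cfg.landmark_jitter_sd, seed=seed)
    models = synthetic.default_taxon_models(cfg.separation)
    if cfg.include_extra_accessions:
        models = models + synthetic.extra_accession_models(cfg.separation)
    if cfg.seeds_per_taxon is not None:
        for m in models:
            m.n_seeds = cfg.seeds_per_taxon
    models = models + synthetic.unknown_mixture_models(
        cfg.n_unknowns, cfg.separation)
    pop = synthetic.simulate_population(models, noise,
                                        px_per_mm=cfg.px_per_mm)
    repeats = {}
    if cfg.include_repeatability:
        triple = [m for m in synthetic.default_taxon_models(cfg.separation)
                  if m.name in ("P_nigrum", "P_setigerum", "P_somniferum")]
        base = synthetic.simulate_population(
            [synthetic.TaxonModel(**{**m.__dict__, "n_seeds": 5})
             for m in triple],
            synthetic.NoiseSpec(seed=seed + 1), px_per_mm=cfg.px_per_mm)
        designs = synthetic.repeatability_noise(seed=seed + 2)
        for test, test_noise in designs.items():
            pops = [synthetic.simulate_repeats(r, 3, test_noise,
                                               px_per_mm=cfg.px_per_mm)
                    for r in base.records]
            repeats[test] = synthetic.SimulatedPopulation(
                records=[x for p in pops for x in p.records],
                masks={k: v for p in pops for k, v in p.masks.items()},
                landmarks={k: v for p in pops for k, v in p.landmarks.items()},
                px_per_mm=cfg.px_per_mm)
    return pop, repeats


def stage_extract(masks: dict, landmarks: dict,
                  scale: float = 1.0) -> tuple[dict, pd.DataFrame]:
    """Trace outlines from masks and measure bounding boxes."""
    outlines, rows = {}, []
    for rid, mask in masks.items():
        out = imaging.extract_outline(mask, scale=scale)
        outlines[rid] = out
        length, width = imaging.bounding_box_size(out)
        rows.append({"id": rid, "length": length, "width": width,
                     "touches_border": out.touches_border})
    return outlines, pd.DataFrame(rows)


def stage_efa(outlines: dict, landmarks: dict, cfg: RunConfig):
    """Procrustes-normalize, transform, and pick the harmonic count.

    GPA is driven by the 5-landmark configurations; aligned outlines are
    resampled to ``k_points`` from the aligned landmark 2 and decomposed at
    ``max_harmonics``; the retained count H* is the smallest H whose mean
    cumulative power reaches ``harmonic_threshold``.  Returns
    (coefficient DataFrame truncated to H*, H*).
    """
    ids = list(outlines.keys())
    aligned = efa.gpa_align([outlines[i] for i in ids],
                            [landmarks[i] for i in ids])
    coeffs = {}
    for rid, out, lm in zip(ids, aligned.outlines, aligned.landmarks):
        rs = efa.resample_outline(out, cfg.k_points, start=lm[1])
        coeffs[rid] = efa.efourier(rs, cfg.max_harmonics)
    h_star = efa.choose_harmonics(coeffs.values(), cfg.harmonic_threshold,
                                  drop_first=cfg.harmonic_drop_first)
    rows = []
    for rid, c in coeffs.items():
        t = c.truncated(h_star)
        row = {"id": rid}
        for letter, vec in zip("abcd", (t.a, t.b, t.c, t.d)):
            for h, v in enumerate(vec, start=1):
                row[f"{letter}{h}"] = v
        rows.append(row)
    return pd.DataFrame(rows), h_star


def _coeff_cols(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c[:1] in "abcd" and c[1:].isdigit()]


def stage_stats(table: pd.DataFrame, cfg: RunConfig,
                repeats_tables: dict | None = None) -> dict:
    """Statistical suite on the analysis table (knowns vs unknowns)."""
    known = table[table["taxon"] != "unknown"]
    unknown = table[table["taxon"] == "unknown"]
    res: dict = {"univariate": {}, "pairwise_wilcoxon": {}}
    for var, col in (("length", "log_length"), ("width", "log_width"),
                     ("cells", "cells")):
        chi2, df_, p = morphostats.kruskal_wallis(known[col].to_numpy(),
                                                  known["taxon"].to_numpy())
        res["univariate"][var] = {"chi2": chi2, "df": df_, "p": p}
        res["pairwise_wilcoxon"][var] = morphostats.pairwise_wilcoxon(
            known[col].to_numpy(), known["taxon"].to_numpy())
    cols = _coeff_cols(table)
    pca = morphostats.pca_fit(known[cols].to_numpy())
    res["pca"] = pca
    res["pca_supplementary"] = (
        morphostats.pca_project(pca, unknown[cols].to_numpy())
        if len(unknown) else np.empty((0, len(pca.explained))))
    res["permanova"] = morphostats.permutational_manova(
        known[cols].to_numpy(), known["taxon"].to_numpy(),
        n_perm=999, seed=cfg.stage_seed("stats"))
    grouped = {t: g[cols].to_numpy() for t, g in known.groupby("taxon")}
    shapes = morphostats.mean_shapes(grouped, k=cfg.k_points)
    res["mean_shapes"] = shapes
    res["upgma_newick"] = morphostats.upgma_tree(
        {t: c for t, (c, _o) in shapes.items()})
    if repeats_tables:
        me = {}
        for test, rt in repeats_tables.items():
            per_taxon = {}
            for taxon, grp in rt.groupby("taxon"):
                indiv = grp["id"].str.rsplit("_r", n=1).str[0]
                frame = morphostats.shape_measurement_error(
                    grp[_coeff_cols(rt)].to_numpy(), indiv.to_numpy())
                pooled = frame.loc[frame["component"] == "pooled",
                                   "pct_me"].iloc[0]
                pc1 = frame.iloc[0]
                per_taxon[taxon] = {"pct_me_pooled": float(pooled),
                                    "pct_me_pc1": float(pc1["pct_me"]),
                                    "F_pc1": float(pc1["F"]),
                                    "p_pc1": float(pc1["p"])}
            me[test] = per_taxon
        res["measurement_error"] = me
    return res


def stage_classify(table: pd.DataFrame, cfg: RunConfig) -> dict:
    known = table[table["taxon"] != "unknown"]
    seed = cfg.stage_seed("classify")
    reports = classify.balanced_benchmark(
        known, cfg.feature_sets, n_per_class=cfg.n_per_class,
        n_perm=cfg.n_perm_benchmark, seed=seed)
    baseline, _ = classify.shuffled_label_baseline(
        known, "all" if "all" in cfg.feature_sets else cfg.feature_sets[0],
        n_per_class=cfg.n_per_class,
        n_perm=min(cfg.n_perm_benchmark, 100), seed=seed + 1)
    for rep in reports.values():
        rep.baseline_max_accuracy = baseline
    return reports


def stage_assign(table: pd.DataFrame, cfg: RunConfig) -> dict:
    known = table[table["taxon"] != "unknown"]
    unknown = table[table["taxon"] == "unknown"]
    if not len(unknown):
        return {}
    seed = cfg.stage_seed("assign")
    out = {}
    for fs in cfg.feature_sets:
        results, comp = classify.assign_unknowns(
            known, unknown, fs, n_per_class=cfg.n_per_class,
            n_perm=cfg.n_perm_assign, seed=seed)
        out[fs] = {"results": results, "composition": comp}
    return out


# ---------------------------------------------------------------------------
# orchestration

def _build_table(records_df: pd.DataFrame, measured: pd.DataFrame,
                 coeff_df: pd.DataFrame) -> pd.DataFrame:
    """Analysis table: identity + cells from the descriptor records,
    length/width measured on the extracted outlines, shape coefficients."""
    table = records_df[["id", "taxon", "cells"]].merge(
        measured[["id", "length", "width"]], on="id")
    table["log_length"] = np.log(table["length"])
    table["log_width"] = np.log(table["width"])
    return table.merge(coeff_df, on="id")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the machine-readable summary.

    Artifacts (records, coefficients, statistics, benchmark, assignments,
    the Newick tree and summary.json) are written under ``cfg.outdir``.
    Rerunning with an identical config reproduces every output.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    summary: dict = {"config": asdict(cfg)}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        repeats = {}
        if cfg.simulate:
            pop, repeats = stage_simulate(cfg)
            masks, landmarks = pop.masks, pop.landmarks
            records_df = pop.to_frame()
        else:
            if not (cfg.masks_dir and cfg.landmarks_path
                    and cfg.descriptors_path):
                raise ValueError("non-simulated runs need masks_dir, "
                                 "landmarks_path and descriptors_path")
            masks = {p.stem: imaging.read_mask(p)
                     for p in sorted(Path(cfg.masks_dir).glob("*.png"))}
            landmarks = imaging.read_landmarks(cfg.landmarks_path)
            records_df = imaging.read_descriptor_table(cfg.descriptors_path)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        _stage("extract")
        outlines, measured = stage_extract(masks, landmarks,
                                           scale=1.0 / cfg.px_per_mm)
    except Exception as e:
        raise RuntimeError(f"stage 'extract' failed: {e}") from e

    try:
        _stage("efa")
        coeff_df, h_star = stage_efa(outlines, landmarks, cfg)
        summary["h_star"] = h_star
        table = _build_table(records_df, measured, coeff_df)
        table.to_csv(outdir / "analysis_table.csv", index=False)
        repeats_tables = {}
        for test, rpop in repeats.items():
            r_outlines, r_measured = stage_extract(
                rpop.masks, rpop.landmarks, scale=1.0 / cfg.px_per_mm)
            r_coeffs, _ = stage_efa(r_outlines, rpop.landmarks, cfg)
            repeats_tables[test] = _build_table(
                rpop.to_frame(), r_measured, r_coeffs)
    except Exception as e:
        raise RuntimeError(f"stage 'efa' failed: {e}") from e

    try:
        _stage("stats")
        st = stage_stats(table, cfg, repeats_tables)
        summary["univariate"] = st["univariate"]
        summary["permanova"] = {
            "F": st["permanova"].F, "r2": st["permanova"].r2,
            "adj_r2": st["permanova"].adj_r2, "p": st["permanova"].p,
            "df_between": st["permanova"].df_between}
        summary["pca_explained"] = [float(x)
                                    for x in st["pca"].explained[:5]]
        summary["upgma_newick"] = st["upgma_newick"]
        if "measurement_error" in st:
            summary["measurement_error"] = st["measurement_error"]
        (outdir / "upgma_tree.nwk").write_text(st["upgma_newick"] + "\n")
        known_mask = table["taxon"] != "unknown"
        scores = pd.DataFrame(
            np.vstack([st["pca"].scores[:, :5],
                       st["pca_supplementary"][:, :5]])
            if len(st["pca_supplementary"]) else st["pca"].scores[:, :5],
            columns=[f"PC{i+1}" for i in range(min(
                5, st["pca"].scores.shape[1]))])
        scores["id"] = list(table.loc[known_mask, "id"]) + \
            list(table.loc[~known_mask, "id"])
        scores["is_supplementary"] = [False] * int(known_mask.sum()) + \
            [True] * int((~known_mask).sum())
        scores.to_csv(outdir / "pca_scores.csv", index=False)
        tidy = []
        for var, r in st["univariate"].items():
            tidy.append({"test": "kruskal_wallis", "variable": var,
                         "statistic": r["chi2"], "df": r["df"], "p": r["p"]})
        pd.DataFrame(tidy).to_csv(outdir / "stat_tests.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage 'stats' failed: {e}") from e

    try:
        _stage("classify")
        reports = stage_classify(table, cfg)
        bench_rows = []
        for fs, rep in reports.items():
            frame = rep.per_class_accuracy.assign(feature_set=fs)
            bench_rows.append(frame)
        bench = pd.concat(bench_rows, ignore_index=True)
        bench.to_csv(outdir / "benchmark.csv", index=False)
        summary["benchmark"] = {
            fs: {str(cls): float(acc) for cls, acc in
                 rep.per_class_accuracy.groupby("class")["accuracy"]
                 .mean().items()}
            for fs, rep in reports.items()}
        summary["baseline_max_accuracy"] = float(
            next(iter(reports.values())).baseline_max_accuracy)
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    try:
        _stage("assign")
        assignments = stage_assign(table, cfg)
        if assignments:
            rows = []
            for fs, a in assignments.items():
                for r in a["results"]:
                    row = {"feature_set": fs, "seed_id": r.seed_id,
                           "predicted": r.predicted,
                           "vote_share": r.vote_share,
                           "ambiguous": r.ambiguous}
                    row.update({f"votes_{k}": v for k, v in r.votes.items()})
                    rows.append(row)
            pd.DataFrame(rows).to_csv(outdir / "assignments.csv", index=False)
            summary["assignment_composition"] = {
                fs: {str(k): int(v) for k, v in a["composition"].items()}
                for fs, a in assignments.items()}
    except Exception as e:
        raise RuntimeError(f"stage 'assign' failed: {e}") from e

    text = json.dumps(summary, indent=2, sort_keys=True, default=str)
    (outdir / "summary.json").write_text(text)
    summary["summary_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return summary
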