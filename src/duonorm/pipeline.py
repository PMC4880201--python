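"""End-to-end orchestration of the three-experiment workflow.

For each experiment the probe-level data is normalized both ways, each
route gets moderated statistics and a jack-knifed OPLS-DA model, and the
two routes are fused into a candidate set and direction-split top-N
subsets.  The cross-experiment union is profile-clustered per
normalization, matched across normalizations, and the up-regulated
subsets are footprinted against background promoters.  Every stage emits
plain-text artifacts plus a JSON run report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus, enrich, footprint, io, modstats, normalize, oplsda, profiles, synthdata

__all__ = ["ExperimentSpec", "PipelineConfig", "run_all", "analyze_experiment", "load_series_matrix"]

log = logging.getLogger("duonorm")


@dataclass
class ExperimentSpec:
    tag: str  # CONSOL / REC / EXTNOR
    synth: synthdata.SyntheticConfig
    probe_path: str | None = None  # optional pre-generated probe TSV


@dataclass
class PipelineConfig:
    experiments: list[ExperimentSpec]
    r: float = 0.75
    vip_min: float = 1.0
    top_n: int = 200
    n_orth: int = 1
    n_folds: int = 7
    k: int = 6
    restarts: int = 1000
    unchanged_eps: float = 0.10
    ease_cutoff: float = 0.01
    kappa_threshold: float = 0.7
    min_terms: int = 3
    min_genes: int = 5
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, n_probesets: int = 2000, de_fraction: float = 0.05,
                effect_log2: float = 1.0) -> "PipelineConfig":
        exps = []
        for i, (tag, n) in enumerate([("CONSOL", 8), ("REC", 8), ("EXTNOR", 6)]):
            exps.append(
                ExperimentSpec(
                    tag=tag,
                    synth=synthdata.SyntheticConfig(
                        n_probesets=n_probesets,
                        n_per_group=(n, n),
                        de_fraction=de_fraction,
                        effect_log2=effect_log2,
                        seed=seed * 1000 + i,
                    ),
                )
            )
        return cls(experiments=exps, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_yaml(path)
        exps = [
            ExperimentSpec(
                tag=e["tag"],
                synth=synthdata.SyntheticConfig(**{
                    **e.get("synth", {}),
                    "n_per_group": tuple(e.get("synth", {}).get("n_per_group", (6, 6))),
                }),
                probe_path=e.get("probe_path"),
            )
            for e in raw.pop("experiments")
        ]
        return cls(experiments=exps, **raw)


@dataclass
class ExperimentResult:
    tag: str
    dataset: synthdata.ProbeLevelDataset
    stats: dict[str, consensus.PerProbeStats]
    candidates: consensus.CandidateSet
    up: consensus.ExpressionSubset
    down: consensus.ExpressionSubset


def _route_stats(
    matrix: normalize.ExpressionMatrix,
    dataset: synthdata.ProbeLevelDataset,
    cfg: PipelineConfig,
) -> consensus.PerProbeStats:
    """Moderated stats + jack-knifed OPLS-DA for one normalization route."""
    design = modstats.GroupDesign(
        assignment={s: g for s, g in zip(matrix.sample_ids, dataset.group_labels)},
        contrast=dataset.groups,
    )
    mod = modstats.fit_moderated_t(matrix, design)

    x = matrix.values.T  # samples x probesets
    lower, _upper, model = oplsda.jackknife_vip_ci(
        x,
        dataset.group_labels,
        cv=oplsda.CvSpec(n_folds=cfg.n_folds, seed=cfg.seed),
        n_orth=cfg.n_orth,
        positive_level=dataset.groups[0],
    )
    scaled = oplsda.pareto_scale(x)
    if scaled.dropped:
        raise ValueError(f"constant probesets: {scaled.dropped[:5]}")
    return consensus.make_probe_table(
        matrix.probeset_ids, mod.log2fc, mod.p, model.pcorr, model.vip, lower
    )


def analyze_experiment(
    dataset: synthdata.ProbeLevelDataset, cfg: PipelineConfig, tag: str
) -> ExperimentResult:
    mats = {"mas": normalize.mas5_like(dataset), "rma": normalize.rma(dataset)}
    stats = {k: _route_stats(m, dataset, cfg) for k, m in mats.items()}
    cand = consensus.select_candidates(
        stats["mas"], stats["rma"], r=cfg.r, vip_min=cfg.vip_min, experiment=tag
    )
    up, down = consensus.rank_and_split(
        cand, n=cfg.top_n, tags=(f"{tag}_up", f"{tag}_down")
    )
    return ExperimentResult(tag=tag, dataset=dataset, stats=stats,
                            candidates=cand, up=up, down=down)


def _recovery(candidates: consensus.CandidateSet, truth: dict[str, float]) -> dict:
    selected = set(candidates.selected.index)
    truth_ids = set(truth)
    tp = len(selected & truth_ids)
    sensitivity = tp / len(truth_ids) if truth_ids else float("nan")
    precision = tp / len(selected) if selected else float("nan")
    return {
        "n_selected": len(selected),
        "n_truth": len(truth_ids),
        "true_positives": tp,
        "sensitivity": sensitivity,
        "precision": precision,
        "false_discovery_rate": 1.0 - precision if selected else float("nan"),
    }


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full workflow; writes per-stage artifacts and a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "experiments"},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "experiments": {},
    }

    results: list[ExperimentResult] = []
    for spec in cfg.experiments:
        log.info("experiment %s: generating/loading probe data", spec.tag)
        if spec.probe_path:
            dataset = io.read_probe_tsv(spec.probe_path)
        else:
            dataset = synthdata.gen_probe_data(spec.synth)
        res = analyze_experiment(dataset, cfg, spec.tag)
        results.append(res)
        res.candidates.records.to_csv(outdir / f"candidates_{spec.tag}.tsv", sep="\t")
        rec = _recovery(res.candidates, dataset.truth)
        report["experiments"][spec.tag] = {
            "n_candidates": res.candidates.n_selected,
            "top_up": len(res.up.probesets),
            "top_down": len(res.down.probesets),
            "recovery": rec,
        }

    # cross-experiment union (top-N mode) and fold-change profiles
    subsets = [s for r in results for s in (r.up, r.down)]
    subset_exp = {s.tag: r.tag for r in results for s in (r.up, r.down)}
    fc_pairs = {
        r.tag: r.candidates.records[["log2fc_mas", "log2fc_rma"]] for r in results
    }
    cre = consensus.build_cre(subsets, fc_pairs, subset_exp)
    report["cre_size"] = len(cre)
    (outdir / "cre_members.txt").write_text("\n".join(sorted(cre)) + "\n")

    matched_report = []
    if len(cre) >= cfg.k:
        cre_sorted = sorted(cre)
        clusterings = {}
        for norm_key in ("mas", "rma"):
            prof = _fc_lookup(results, norm_key, cre_sorted)
            clusterings[norm_key] = profiles.kmeans_profiles(
                prof, cre_sorted, k=cfg.k, restarts=cfg.restarts, seed=cfg.seed,
                normalization_tag=norm_key,
            )
        matched = profiles.match_profiles(
            clusterings["mas"], clusterings["rma"],
            unchanged_eps=cfg.unchanged_eps,
        )
        matched_report = [
            {
                "clusters": [m.cluster_mas, m.cluster_rma],
                "n_members": len(m.members),
                "sign_pattern": list(m.sign_pattern),
                "jaccard": m.jaccard,
            }
            for m in matched
        ]
    report["matched_profiles"] = matched_report

    # enrichment on each experiment's up-subset against planted annotations
    enr_report = {}
    for spec, res in zip(cfg.experiments, results):
        annot = synthdata.gen_annotations(spec.synth, set(res.dataset.truth))
        enr = enrich.enrich_all(res.up.probesets, annot, ease_cutoff=cfg.ease_cutoff,
                                min_genes=cfg.min_genes)
        clusters = enrich.cluster_terms(
            enr, res.up.probesets, kappa_threshold=cfg.kappa_threshold,
            min_terms=cfg.min_terms, ease_cutoff=cfg.ease_cutoff,
        )
        enr_report[spec.tag] = {
            "n_significant_terms": len(enrich.significant(enr, cfg.ease_cutoff)),
            "n_clusters": len(clusters),
        }
    report["enrichment"] = enr_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _fc_lookup(results: list[ExperimentResult], norm_key: str, ids: list[str]) -> np.ndarray:
    cols = []
    for r in results:
        col = r.candidates.records[f"log2fc_{norm_key}"].reindex(ids).fillna(0.0).to_numpy()
        cols.append(col)
    return np.column_stack(cols)


def load_series_matrix(path: str | Path):
    """Parse a GEO series-matrix text file into an ExpressionMatrix.

    Optional convenience loader; only the sample table header and the
    expression block between the table-begin/table-end markers are used.
    """
    sample_ids: list[str] = []
    rows: list[tuple[str, list[float]]] = []
    in_table = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if not in_table:
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if not sample_ids:
                if parts[0] != "ID_REF":
                    raise ValueError(f"line {lineno}: expected ID_REF header, got {parts[0]!r}")
                sample_ids = parts[1:]
                continue
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(f"line {lineno}: expected {len(sample_ids) + 1} fields")
            rows.append((parts[0], [float(v) for v in parts[1:]]))
    if not sample_ids:
        raise ValueError("no series matrix table found")
    values = np.array([v for _, v in rows])
    return normalize.ExpressionMatrix(values, [r for r, _ in rows], sample_ids, "series")
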