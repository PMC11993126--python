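"""End-to-end orchestration: simulate -> metrics -> stats -> tree -> cluster.

A single :class:`RunConfig` drives the whole analysis; every random stage
draws from an independent substream of one master seed, so e.g. changing
the bootstrap resample count never perturbs the generated cohort.  All
outputs carry a provenance block (seed, resolved parameters, package
version) and runs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import bootstrap_jaccard, hclust_complete, majority_accuracy
from .cohort import (DEFAULT_GROUP_SIZES, MD_FEATURES, default_templates,
                     generate_cohort, measure_cohort)
from .group_stats import kruskal_wallis_holm
from .metrics import cohort_md_profiles
from .normative import NormativeModel, default_normative_model
from .stimulus import default_device
from .tree import TreeFitParams, evaluate, fit_cart, prune_tree

#: Fixed substream labels: stage -> spawn key under the master seed.
_STAGES = ("cohort", "measure", "bootstrap")

LONG_COLUMNS = {"patient_id", "group", "age", "eye", "session", "receptor",
                "frequency_hz", "threshold_contrast"}
WIDE_COLUMNS = {"patient_id", "group"} | set(MD_FEATURES)


@dataclass
class RunConfig:
    seed: int = 0
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_eyes: int = 1
    sessions_per_eye: int = 1
    measure_method: str = "staircase"
    minsplit: int = 5
    cp: float = 0.1
    k_clusters: int = 4
    n_bootstrap: int = 100
    missing_policy: str = "drop"
    normative_path: str | None = None
    out_dir: str = "photopheno_run"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["group_sizes"] = dict(self.group_sizes)
        return d


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Named, independent substream of the master seed."""
    return np.random.SeedSequence(entropy=master, spawn_key=(_STAGES.index(stage),))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes the report bundle and returns paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"photopheno_version": __version__, "config": config.to_dict()}

    normative = (NormativeModel.from_yaml(config.normative_path)
                 if config.normative_path else default_normative_model())

    stage = "device"
    try:
        device = default_device()
        stage = "simulate"
        observers = generate_cohort(default_templates(), config.group_sizes,
                                    normative, seed=stage_seed(config.seed, "cohort"))
        raw = measure_cohort(observers, device.max_contrasts, normative,
                             n_eyes=config.n_eyes,
                             sessions_per_eye=config.sessions_per_eye,
                             seed=stage_seed(config.seed, "measure"),
                             method=config.measure_method)
        raw.to_csv(out / "cohort.csv", index=False)

        stage = "metrics"
        md = cohort_md_profiles(raw, normative, missing_policy=config.missing_policy)
        md.to_csv(out / "md_profiles.csv", index=False)

        stage = "stats"
        comparisons = kruskal_wallis_holm(md)
        with open(out / "stats_report.json", "w") as fh:
            json.dump({"provenance": provenance,
                       "features": [c.to_dict() for c in comparisons]}, fh, indent=2)

        stage = "tree"
        full = fit_cart(md, TreeFitParams(minsplit=config.minsplit))
        pruned = prune_tree(full, config.cp)
        cm = evaluate(pruned, md)
        with open(out / "tree.json", "w") as fh:
            json.dump({"provenance": provenance, "tree": pruned.to_dict(),
                       "confusion": cm.to_dict()}, fh, indent=2)

        stage = "cluster"
        dend = hclust_complete(md)
        assignment = dend.cut(k=config.k_clusters)
        majority = majority_accuracy(assignment, md["group"].to_numpy())
        stability = bootstrap_jaccard(md, k=config.k_clusters,
                                      n_bootstrap=config.n_bootstrap,
                                      seed=stage_seed(config.seed, "bootstrap"))
        with open(out / "clusters.json", "w") as fh:
            json.dump({"provenance": provenance,
                       "merges": [[int(a), int(b), float(h)] for a, b, h in dend.merges],
                       "labels": {pid: int(lab) for pid, lab in
                                  zip(md["patient_id"], assignment.labels)},
                       "majority": majority.to_dict(),
                       "stability": stability.to_dict()}, fh, indent=2)

        stage = "report"
        _write_report(out / "report.md", provenance, md, comparisons, pruned, cm,
                      assignment, majority, stability)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed; inputs under {out}") from err

    return {"out_dir": str(out),
            "files": [str(out / f) for f in ("cohort.csv", "md_profiles.csv",
                                             "stats_report.json", "tree.json",
                                             "clusters.json", "report.md")]}


def _write_report(path: Path, provenance: dict, md: pd.DataFrame, comparisons,
                  pruned, cm, assignment, majority, stability) -> None:
    lines = ["# photopheno run report", "",
             f"- package version: {provenance['photopheno_version']}",
             f"- seed: {provenance['config']['seed']}",
             f"- patients: {len(md)}", "",
             "## Group means (dB)", "",
             md.groupby("group")[list(MD_FEATURES)].mean().round(2).to_markdown(), "",
             "## Kruskal-Wallis (Holm-corrected across the six features)", ""]
    for c in comparisons:
        lines.append(f"- {c.feature}: H = {c.kw_statistic:.2f}, "
                     f"p(raw) = {c.kw_p_raw:.3g}, p(Holm) = {c.kw_p_holm:.3g}")
    lines += ["", "## Pruned decision tree", "", "```", pruned.rules_text(), "```", "",
              f"Resubstitution accuracy {cm.accuracy:.2f} "
              f"(95% CI {cm.ci95[0]:.2f}-{cm.ci95[1]:.2f}), n = {cm.n}", "",
              "Confusion matrix (rows = true, columns = predicted):", "",
              pd.DataFrame(cm.counts.astype(int), index=cm.classes,
                           columns=cm.classes).to_markdown(), "",
              "## Hierarchical clustering (complete linkage, Euclidean)", "",
              pd.crosstab(md["group"], assignment.labels).to_markdown(), "",
              f"Majority-diagnosis accuracy {majority.accuracy:.2f} "
              f"(95% CI {majority.ci95[0]:.2f}-{majority.ci95[1]:.2f})", "",
              "Bootstrap stability (mean Jaccard; stable if > "
              f"{stability.threshold}):", ""]
    for c, j in sorted(stability.mean_jaccard.items()):
        flag = "stable" if stability.stable[c] else "unstable"
        lines.append(f"- cluster {c}: {j:.2f} ({flag})")
    path.write_text("\n".join(lines) + "\n")


def load_cohort_csv(path: str) -> tuple[str, pd.DataFrame]:
    """Auto-detect and validate one of the two documented schemas.

    Returns ("long", frame) for raw measurement tables or ("wide", frame)
    for precomputed MD-profile tables.
    """
    table = pd.read_csv(path)
    cols = set(table.columns)
    if LONG_COLUMNS - {"censored"} <= cols:
        kind = "long"
        if "censored" not in cols:
            import warnings
            warnings.warn("long cohort table lacks a 'censored' column; assuming none censored")
            table["censored"] = False
        numeric = ["age", "frequency_hz", "threshold_contrast"]
        keys = ["patient_id", "eye", "session", "receptor", "frequency_hz"]
    elif WIDE_COLUMNS <= cols:
        kind = "wide"
        numeric = list(MD_FEATURES)
        keys = ["patient_id"]
    else:
        raise ValueError(
            f"unrecognized cohort schema in {path}: columns {sorted(cols)}; expected the "
            f"long raw schema {sorted(LONG_COLUMNS)} or the wide MD schema {sorted(WIDE_COLUMNS)}")
    bad_rows = [int(i) for c in numeric
                for i in table.index[pd.to_numeric(table[c], errors="coerce").isna()
                                     & table[c].notna()]]
    if bad_rows:
        raise ValueError(f"non-numeric cells in rows {sorted(set(bad_rows))}")
    dupes = table.duplicated(subset=keys)
    if dupes.any():
        raise ValueError(f"duplicate keys in rows {table.index[dupes].tolist()}")
    return kind, table
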