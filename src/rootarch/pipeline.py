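"""Pipeline orchestration: simulate -> extract -> stats -> classify.

A single structured config (YAML on disk, :class:`RunConfig` in
memory) drives the four stages; every run produces a versioned JSON
report recording parameters, per-stage counts and warnings, and a
SHA-256 digest of every output file, so identical config + seed can be
verified to reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd
import yaml

from . import classify as _classify
from . import image_io, stats, synthetic, traits

log = logging.getLogger("rootarch")

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline",
           "extract_traits_batch", "stats_outputs", "classify_outputs"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the package defaults."""

    out_dir: str = "rootarch_out"
    seed: int = 0

    # simulate stage (skipped when n_genotypes is 0 and images_dir given)
    simulate: bool = True
    n_genotypes: int = 10
    n_replications: int = 2
    px_per_cm: float = 50.0
    canvas_cm: tuple[float, float] = (24.0, 22.0)

    # extract stage inputs (used when simulate is False)
    images_dir: str | None = None
    weights_csv: str | None = None
    metadata_csv: str | None = None

    # extraction conventions
    threshold_method: str = "otsu"
    threshold: float | None = None
    min_component_px: int | None = None
    length_method: str = "pixel"
    sweep_source: str = "skeleton"
    percentile_method: str = "nearest_rank"

    # classification
    k: int = 3
    linkage: str = "ward"
    cluster_on: str = "pca"
    n_pca_components: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            try:
                doc = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"cannot parse config {path}: {exc}") from exc
        findings = validate_config(doc)
        if findings:
            raise ValueError("invalid config:\n  " + "\n  ".join(findings))
        if "canvas_cm" in doc:
            doc["canvas_cm"] = tuple(doc["canvas_cm"])
        return cls(**doc)


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(doc: dict) -> list[str]:
    """Check a parsed config document; an empty list means runnable.

    Reports unknown keys (with a nearest-match suggestion), bad value
    ranges and missing input paths.
    """
    findings: list[str] = []
    if not isinstance(doc, dict):
        return [f"config must be a mapping, got {type(doc).__name__}"]
    for key in doc:
        if key not in _FIELD_NAMES:
            hint = difflib.get_close_matches(key, _FIELD_NAMES, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            findings.append(f"unknown key {key!r}{suffix}")

    merged = {**{f.name: f.default for f in dataclasses.fields(RunConfig)}, **doc}
    if not merged["simulate"]:
        for key in ("images_dir", "weights_csv", "metadata_csv"):
            val = merged.get(key)
            if val is None:
                findings.append(f"{key} is required when simulate is false")
            elif not Path(val).exists():
                findings.append(f"{key} path does not exist: {val}")
    for key in ("px_per_cm",):
        if key in doc and not (isinstance(doc[key], (int, float)) and doc[key] > 0):
            findings.append(f"{key} must be a positive number, got {doc[key]!r}")
    if "k" in doc and (not isinstance(doc["k"], int) or doc["k"] < 2):
        findings.append(f"k must be an integer >= 2, got {doc['k']!r}")
    if "linkage" in doc and doc["linkage"] not in ("complete", "average",
                                                   "single", "ward"):
        findings.append(f"unknown linkage {doc['linkage']!r}")
    if "seed" in doc and not isinstance(doc["seed"], int):
        findings.append(f"seed must be an integer, got {doc['seed']!r}")
    return findings


@dataclass
class RunReport:
    """Record of one pipeline run."""

    schema_version: int = REPORT_SCHEMA_VERSION
    config: dict = field(default_factory=dict)
    config_digest: str = ""
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)      # path -> sha256
    status: str = "ok"
    error: str | None = None

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, indent=1, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def extract_traits_batch(
    images_dir: str | Path,
    metadata_csv: str | Path,
    weights_csv: str | Path | None,
    px_per_cm: float,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Extract the full trait vector for every plant in a metadata table.

    Returns a wide per-plant table: plant_id, genotype, environment,
    replication, then one column per trait abbreviation.
    """
    config = config or RunConfig()
    meta = pd.read_csv(metadata_csv)
    weights = None
    if weights_csv is not None:
        weights = pd.read_csv(weights_csv).set_index("plant_id")
    rows = []
    for rec in meta.itertuples(index=False):
        path = Path(images_dir) / f"{rec.plant_id}.png"
        scan = image_io.load_scan(path, px_per_cm=px_per_cm)
        mask = image_io.binarize(
            scan, method=config.threshold_method, threshold=config.threshold,
            min_component_px=config.min_component_px,
        )
        w = None
        if weights is not None and rec.plant_id in weights.index:
            w = (float(weights.loc[rec.plant_id, "SDW_g"]),
                 float(weights.loc[rec.plant_id, "RDW_g"]))
        tv = traits.compute_all(
            mask, weights=w,
            length_method=config.length_method,
            sweep_source=config.sweep_source,
            percentile_method=config.percentile_method,
        )
        row = {"plant_id": rec.plant_id, "genotype": rec.genotype,
               "environment": rec.environment, "replication": rec.replication}
        row.update(tv.as_dict())
        rows.append(row)
        log.info("extracted %s", rec.plant_id)
    return pd.DataFrame(rows)


def traits_wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    id_cols = ["genotype", "environment", "replication"]
    value_cols = [c for c in wide.columns if c in traits.TRAIT_NAMES]
    long = wide.melt(id_vars=id_cols, value_vars=value_cols,
                     var_name="trait", value_name="value")
    return long.dropna(subset=["value"]).reset_index(drop=True)


def stats_outputs(long: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-trait summary (means, s.d., h2, E/G/GxE significance) and the
    long-format correlation table."""
    summary = stats.trait_summary(long)
    rows = []
    for trait in summary.index:
        try:
            an = stats.anova_ge(long, trait)
            vc = stats.variance_components(an)
            h2 = stats.heritability(vc)
            rows.append({
                "trait": trait,
                "E": stats.significance_stars(an["E"].p),
                "G": stats.significance_stars(an["G"].p),
                "GxE": stats.significance_stars(an["G:E"].p),
                "h2": h2,
                "sigma_g": vc.sigma_g, "sigma_ge": vc.sigma_ge,
                "sigma_gr": vc.sigma_gr, "sigma_ger": vc.sigma_ger,
            })
        except ValueError as exc:
            rows.append({"trait": trait, "E": "NA", "G": "NA", "GxE": "NA",
                         "h2": float("nan"), "note": str(exc)})
    anova_df = pd.DataFrame(rows).set_index("trait")
    table2 = summary.join(anova_df)
    corr = stats.correlation_matrix(long)
    return {"trait_table": table2.reset_index(), "correlations": corr.to_long()}


def classify_outputs(long: pd.DataFrame, k: int = 3,
                     linkage: str = "ward", cluster_on: str = "pca",
                     n_components: int = 2) -> dict:
    """Per-environment z-scores, PCA, clustering with size labels, the
    HP->LP transition summary and tanglegram serializations.

    ``cluster_on="pca"`` (default) clusters the genotype scores on the
    first ``n_components`` principal components, following the
    PCA-based classification procedure; ``cluster_on="traits"``
    clusters the full z-scored trait matrix instead.
    """
    means = (long.groupby(["genotype", "environment", "trait"])["value"]
             .mean().unstack("trait"))
    out: dict = {"labels": {}, "pca": {}}
    for env in sorted(long["environment"].unique()):
        z = _classify.zscore(means.xs(env, level="environment"))
        model = _classify.pca(z)
        if cluster_on == "pca":
            basis = dataclasses.replace(
                z, values=model.scores.iloc[:, :n_components])
        elif cluster_on == "traits":
            basis = z
        else:
            raise ValueError(f"unknown cluster_on {cluster_on!r}")
        labels = _classify.cluster(basis, k=k, linkage=linkage, environment=env)
        if k == 3:
            labels = _classify.assign_size_labels(labels, z)
        out["labels"][env] = labels
        out["pca"][env] = model
    if k == 3 and {"HP", "LP"} <= set(out["labels"]):
        out["transitions"] = _classify.transition_matrix(
            out["labels"]["HP"], out["labels"]["LP"])
        out["tanglegram"] = _classify.tanglegram_export(
            out["labels"]["HP"], out["labels"]["LP"])
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full pipeline, short-circuiting on the first stage error.

    Writes all tabular outputs under ``config.out_dir`` and a
    ``report.json`` with content digests; returns the report object.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_doc = dataclasses.asdict(config)
    report = RunReport(
        config=cfg_doc,
        config_digest=hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True, default=str).encode()).hexdigest(),
    )

    def record(stage: str, **info) -> None:
        report.stages.append({"stage": stage, **info})

    def save_csv(df: pd.DataFrame, name: str, **kw) -> Path:
        path = out_dir / name
        df.to_csv(path, index=False, **kw)
        return path

    try:
        # --- simulate ------------------------------------------------
        if config.simulate:
            sim_cfg = synthetic.SimulationConfig(
                n_genotypes=config.n_genotypes,
                n_replications=config.n_replications,
                seed=config.seed,
            )
            sim = synthetic.generate_experiment(
                sim_cfg, out_dir=out_dir, px_per_cm=config.px_per_cm,
                canvas_cm=config.canvas_cm)
            images_dir = sim["images_dir"]
            metadata_csv = sim["metadata_csv"]
            weights_csv = sim["weights_csv"]
            record("simulate", n_plants=sim["n_plants"],
                   px_per_cm=config.px_per_cm)
        else:
            for key in ("images_dir", "weights_csv", "metadata_csv"):
                val = getattr(config, key)
                if val is None or not Path(val).exists():
                    raise FileNotFoundError(f"{key} missing or absent: {val}")
            images_dir = config.images_dir
            metadata_csv = config.metadata_csv
            weights_csv = config.weights_csv
            record("inputs", images_dir=str(images_dir))

        # --- extract -------------------------------------------------
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            wide = extract_traits_batch(images_dir, metadata_csv, weights_csv,
                                        config.px_per_cm, config)
        traits_csv = save_csv(wide, "traits.csv", float_format="%.8g")
        record("extract", n_images=len(wide),
               warnings=[str(w.message) for w in wlist])

        # --- stats ---------------------------------------------------
        long = traits_wide_to_long(wide)
        stat = stats_outputs(long)
        save_csv(stat["trait_table"], "trait_table.csv", float_format="%.6g")
        save_csv(stat["correlations"], "correlations.csv", float_format="%.6g")
        record("stats", n_traits=stat["trait_table"].shape[0])

        # --- classify ------------------------------------------------
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cls = classify_outputs(long, k=config.k, linkage=config.linkage,
                                   cluster_on=config.cluster_on,
                                   n_components=config.n_pca_components)
        label_rows = []
        for env, labels in cls["labels"].items():
            for g in labels.genotypes:
                label_rows.append({
                    "genotype": g, "environment": env,
                    "cluster": int(labels.cluster.loc[g]),
                    "size_label": (labels.size_label.loc[g]
                                   if labels.size_label is not None else ""),
                })
        save_csv(pd.DataFrame(label_rows), "labels.csv")
        scores = pd.concat(
            {env: m.scores.iloc[:, :2] for env, m in cls["pca"].items()},
            names=["environment", "genotype"]).reset_index()
        save_csv(scores, "pca_scores.csv", float_format="%.6g")
        loadings = pd.concat(
            {env: m.loadings.iloc[:, :2] for env, m in cls["pca"].items()},
            names=["environment", "trait"]).reset_index()
        save_csv(loadings, "pca_loadings.csv", float_format="%.6g")
        pca_var = pd.DataFrame(
            [{"environment": env, "component": f"Dim{i+1}", "var_pct": v}
             for env, m in cls["pca"].items()
             for i, v in enumerate(m.var_pct[:5])])
        save_csv(pca_var, "pca_variance.csv", float_format="%.6g")
        extra: list[str] = []
        if "transitions" in cls:
            tr = cls["transitions"]
            trans = tr.matrix_pct.reset_index()
            save_csv(trans, "transitions.csv", float_format="%.6g")
            (out_dir / "transition_summary.json").write_text(json.dumps({
                "same_pct": tr.same_pct, "one_step_pct": tr.one_step_pct,
                "two_step_pct": tr.two_step_pct}, indent=1, sort_keys=True))
            (out_dir / "hp.nwk").write_text(cls["tanglegram"]["hp_newick"] + "\n")
            (out_dir / "lp.nwk").write_text(cls["tanglegram"]["lp_newick"] + "\n")
            save_csv(cls["tanglegram"]["mapping"], "tanglegram_mapping.csv")
            extra = ["transitions.csv", "transition_summary.json",
                     "hp.nwk", "lp.nwk", "tanglegram_mapping.csv"]
        record("classify", k=config.k, linkage=config.linkage,
               warnings=[str(w.message) for w in wlist])

        for name in ["traits.csv", "trait_table.csv", "correlations.csv",
                     "labels.csv", "pca_scores.csv", "pca_loadings.csv",
                     "pca_variance.csv", *extra]:
            report.outputs[name] = _sha256(out_dir / name)
    except Exception as exc:
        report.status = "failed"
        report.error = f"{type(exc).__name__}: {exc}"
        log.error("pipeline failed:\n%s", traceback.format_exc())

    (out_dir / "report.json").write_text(report.to_json())
    return report
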