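"""End-to-end pipeline: association scan, haplotype tables, clinical models.

This is the library's single orchestration entry point; every stage is a
thin call into the analysis modules, and each run writes a manifest with the
seed, configuration hash and input digests so identical inputs reproduce
identical outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__, table2
from .association import run_association_scan
from .clinical import cox_ph, sn_estimator
from .haplotypes import em_haplotype_frequencies, haplotype_case_control
from .io import read_cohort_table
from .types import CaseStatus, CohortTable, Stratum


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class PipelineError(RuntimeError):
    pass


def validate_config(config: Mapping | str | Path) -> dict:
    """Validate a pipeline configuration, reporting all violations at once.

    Accepts a mapping or a path to a JSON/YAML document. Returns the parsed
    config; raises :class:`ConfigError` listing every violation found.
    """
    if not isinstance(config, Mapping):
        path = Path(config)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    violations = []
    if not isinstance(config, Mapping) or not config:
        raise ConfigError(["config must be a non-empty mapping"])
    if "seed" not in config:
        violations.append("missing key: seed")
    elif not isinstance(config["seed"], int):
        violations.append("seed: must be an integer")
    has_counts = config.get("counts") is not None
    has_cohort = config.get("cohort") is not None
    if not has_counts and not has_cohort:
        violations.append("need one of: counts ('table2') or cohort (TSV path)")
    if has_counts and config["counts"] != "table2":
        violations.append(f"counts: unknown fixture {config['counts']!r}")
    if has_cohort and not Path(config["cohort"]).exists():
        violations.append(f"cohort: file not found: {config['cohort']}")
    reps = config.get("reps", 2000)
    if not isinstance(reps, int) or reps < 1000:
        violations.append(f"reps: must be an integer >= 1000, got {reps!r}")
    ci = config.get("ci_method", "woolf")
    if ci not in ("woolf", "bootstrap"):
        violations.append(f"ci_method: must be woolf or bootstrap, got {ci!r}")
    freqs = config.get("haplotype_freqs")
    if freqs is not None:
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            violations.append(f"haplotype_freqs: sum to {total:.6f}, not 1")
    for key in ("min_freq",):
        if key in config and not (0 <= config[key] < 1):
            violations.append(f"{key}: must lie in [0, 1)")
    if violations:
        raise ConfigError(violations)
    return dict(config)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> Path:
    """Run every applicable analysis stage and write TSV outputs + manifest.

    Stages: Table-2-style association scan (always); per-stratum haplotype
    tables (cohort input only); survival and dispersion summaries (cohort
    with clinical columns). Failures mark the manifest and raise
    :class:`PipelineError` after retaining partial outputs.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {
        "command": "run_pipeline",
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "seed": seed,
        "package_version": __version__,
        "inputs": {},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "status": "running",
        "outputs": [],
    }
    failure = None
    try:
        cohort: CohortTable | None = None
        if cfg.get("cohort"):
            path = Path(cfg["cohort"])
            manifest["inputs"][str(path)] = _digest(path)
            cohort = read_cohort_table(path)
            counts = [
                cohort.genotype_counts(snp, stratum)
                for snp in cohort.snp_ids
                for stratum in (Stratum.SMOKERS, Stratum.NEVER_SMOKERS)
            ]
        else:
            counts = table2.builtin_table2_counts()

        scan = run_association_scan(counts, ci_method=cfg.get("ci_method", "woolf"),
                                    reps=cfg.get("reps", 2000), seed=seed)
        _write(scan["snp_table"], out / "assoc.tsv", manifest)
        _write(scan["gene_table"], out / "assoc_genes.tsv", manifest)

        if cohort is not None:
            panel = cfg.get("haplotype_panel", cohort.snp_ids)
            for stratum in (Stratum.SMOKERS, Stratum.NEVER_SMOKERS):
                fc = em_haplotype_frequencies(cohort, panel, status=CaseStatus.CASE,
                                              stratum=stratum)
                fk = em_haplotype_frequencies(cohort, panel, status=CaseStatus.CONTROL,
                                              stratum=stratum)
                tab = haplotype_case_control(
                    fc.frequencies, fk.frequencies, fc.n_individuals, fk.n_individuals,
                    reps=cfg.get("reps", 2000), seed=seed,
                    min_freq=cfg.get("min_freq", 0.01),
                )
                t = tab.table.copy()
                t.attrs["chi2"] = tab.chi2
                _write(t, out / f"haplo_{stratum.value}.tsv", manifest)

            df = cohort.df
            clin_rows = []
            if "age_at_diagnosis" in df.columns and df["age_at_diagnosis"].notna().sum() >= 2:
                sn = sn_estimator(df["age_at_diagnosis"].dropna())
                clin_rows.append({"analysis": "sn_age_at_diagnosis", "value": sn.value,
                                  "n": sn.n})
            if {"survival_time", "event"} <= set(df.columns) and df["event"].notna().any():
                covs = [c for c in cfg.get("survival_covariates", ["stage"])
                        if c in df.columns]
                if covs:
                    fit = cox_ph(cohort, covs)
                    _write(fit.cox.reset_index(), out / "cox.tsv", manifest)
            if clin_rows:
                _write(pd.DataFrame(clin_rows), out / "clinical.tsv", manifest)
    except Exception as exc:
        failure = exc
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
    else:
        manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if failure is not None:
        raise PipelineError(manifest["status"]) from failure
    return out


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# apmstrata {__version__}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"].append(path.name)
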