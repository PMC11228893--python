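"""Shared readers/writers, run configuration, and the staged pipeline driver.

All tabular artifacts are UTF-8, tab-separated TSV with a mandatory header row
and empty fields for missing values; each output carries a provenance comment
line (tool version + config hash) so runs are attributable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import ribocn
from ribocn.cn_estimation import (
    CountingPolicy,
    ConversionConstants,
    RatioEstimate,
    center_adjust,
    estimate_sample,
)
from ribocn.errors import ConfigurationError, ValidationError
from ribocn.reference_prep import read_region_bed

log = logging.getLogger("ribocn")


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    alignment: Path
    center: str


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest TSV (columns sample_id, alignment, center)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "alignment", "center"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing column(s): {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample id(s) in manifest: {dup}")
    if df["center"].isna().any() or (df["center"].str.strip() == "").any():
        raise ValidationError("manifest contains empty center labels")
    entries = [
        ManifestEntry(r.sample_id, Path(r.alignment), r.center)
        for r in df.itertuples(index=False)
    ]
    return SampleManifest(entries)


def _provenance(config_repr: str) -> str:
    digest = hashlib.sha256(config_repr.encode()).hexdigest()[:12]
    return f"# ribocn {ribocn.__version__} config={digest}"


def write_tsv(df: pd.DataFrame, path: str | Path, config_repr: str = "") -> None:
    """Write a TSV with the provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config_repr) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def estimates_to_frame(estimates: list[RatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "region_reads": [e.region_reads for e in estimates],
            "numbered_reads": [e.numbered_reads for e in estimates],
            "ratio": [e.ratio for e in estimates],
            "cn_equivalent": [e.cn_equivalent for e in estimates],
            "center": [e.center for e in estimates],
            "adjusted_ratio": [e.adjusted_ratio for e in estimates],
            "flag": [e.flag for e in estimates],
        }
    )


@dataclass
class RunConfig:
    """Paths, constants and policy switches for a staged pipeline run."""

    manifest: Path | None = None
    regions: Path | None = None
    reference: Path | None = None
    cohort: Path | None = None
    models: list[dict] = field(default_factory=list)
    reference_center: str = "deCODE"
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    policy: CountingPolicy = field(default_factory=CountingPolicy)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        constants = ConversionConstants(
            raw.get("genome_bases", ConversionConstants().genome_bases),
            raw.get("subunit_bases", ConversionConstants().subunit_bases),
        )
        policy = CountingPolicy(
            include_secondary=not raw.get("primary_only", False),
            include_supplementary=not raw.get("primary_only", False),
            include_duplicates=not raw.get("primary_only", False),
        )
        return cls(
            manifest=Path(raw["manifest"]) if "manifest" in raw else None,
            regions=Path(raw["regions"]) if "regions" in raw else None,
            reference=Path(raw["reference"]) if "reference" in raw else None,
            cohort=Path(raw["cohort"]) if "cohort" in raw else None,
            models=raw.get("models", []),
            reference_center=raw.get("reference_center", "deCODE"),
            constants=constants,
            policy=policy,
            seed=int(raw.get("seed", 0)),
        )

    def repr_for_hash(self) -> str:
        return json.dumps(
            {
                "manifest": str(self.manifest),
                "regions": str(self.regions),
                "reference": str(self.reference),
                "cohort": str(self.cohort),
                "models": self.models,
                "reference_center": self.reference_center,
                "constants": [self.constants.genome_bases, self.constants.subunit_bases],
                "seed": self.seed,
            },
            sort_keys=True,
        )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run estimate -> adjust -> derive -> associate, writing per-stage TSVs.

    Stage failures stop the run but retain completed outputs; the summary JSON
    records per-stage status and counts and is written in every case. Returns
    the summary dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = config.repr_for_hash()
    summary: dict = {"version": ribocn.__version__, "seed": config.seed, "stages": {}}

    def finish(status: int) -> dict:
        summary["exit_status"] = status
        (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    estimates: list[RatioEstimate] = []
    try:
        if config.manifest is not None:
            if config.regions is None:
                raise ConfigurationError("estimate stage requires a regions BED")
            manifest = load_manifest(config.manifest)
            regions = read_region_bed(config.regions)
            for entry in manifest:
                estimates.append(
                    estimate_sample(
                        entry.sample_id,
                        entry.alignment,
                        regions,
                        center=entry.center,
                        policy=config.policy,
                        constants=config.constants,
                        reference=config.reference,
                    )
                )
            write_tsv(estimates_to_frame(estimates), out_dir / "estimates.tsv", cfg_repr)
            summary["stages"]["estimate"] = {"status": "ok", "n_samples": len(estimates)}
    except Exception as exc:
        log.error("estimate stage failed: %s", exc)
        summary["stages"]["estimate"] = {"status": "failed", "error": str(exc),
                                         "traceback": traceback.format_exc()}
        return finish(1)

    try:
        if estimates:
            centers = {e.center for e in estimates}
            ref = config.reference_center if config.reference_center in centers else min(centers)
            adjusted = center_adjust(estimates, ref)
            write_tsv(estimates_to_frame(adjusted), out_dir / "adjusted.tsv", cfg_repr)
            summary["stages"]["adjust"] = {"status": "ok", "reference_center": ref}
    except Exception as exc:
        log.error("adjust stage failed: %s", exc)
        summary["stages"]["adjust"] = {"status": "failed", "error": str(exc)}
        return finish(1)

    cohort = None
    try:
        if config.cohort is not None:
            from ribocn.derived_phenotypes import blood_ratios, egfr_table

            cohort = read_tsv(config.cohort)
            blood_cols = {"neutrophils", "lymphocytes", "platelets", "monocytes"}
            if blood_cols <= set(cohort.columns):
                cohort = pd.concat([cohort, blood_ratios(cohort)], axis=1)
            egfr_cols = {"sex", "age", "serum_creatinine", "cystatin_c"}
            if egfr_cols <= set(cohort.columns):
                cohort = egfr_table(cohort)
            write_tsv(cohort, out_dir / "cohort_derived.tsv", cfg_repr)
            summary["stages"]["derive"] = {"status": "ok", "n_participants": len(cohort)}
    except Exception as exc:
        log.error("derive stage failed: %s", exc)
        summary["stages"]["derive"] = {"status": "failed", "error": str(exc)}
        return finish(1)

    try:
        if config.models and cohort is not None:
            from ribocn.association import ModelSpec, fit_association

            rows = []
            for model in config.models:
                spec = ModelSpec(**model)
                res = fit_association(cohort, spec)
                rows.append({"response": spec.response, "exposure": spec.exposure,
                             "family": spec.family, **res.as_dict()})
            write_tsv(pd.DataFrame(rows), out_dir / "associations.tsv", cfg_repr)
            summary["stages"]["associate"] = {"status": "ok", "n_models": len(rows)}
    except Exception as exc:
        log.error("associate stage failed: %s", exc)
        summary["stages"]["associate"] = {"status": "failed", "error": str(exc)}
        return finish(1)

    return finish(0)
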