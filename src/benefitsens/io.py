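"""Configuration, data loading/validation and result serialization."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .estimation import TrialData

__all__ = ["AnalysisConfig", "load_trial_csv", "load_config", "config_hash", "write_results"]

log = logging.getLogger("benefitsens")


@dataclass
class AnalysisConfig:
    """Configuration of one sensitivity analysis run.

    Exactly one of ``delta_grid`` (explicit grid of delta values) or ``A``
    (risk-difference bound, translated to a grid) must be given for a
    sensitivity run.  ``cell`` is ``[x, y]``, ``"auto"`` (variation-
    independent cell of the estimated margins) or ``"largest-stratum"``.
    """

    treatment: str = "X"
    outcome: str = "Y"
    covariates: list[str] = field(default_factory=list)
    cell: object = "auto"
    delta_grid: list[float] | None = None
    A: float | None = None
    formula: str | None = None
    mode: str = "joint"
    inference: str = "sandwich"
    B: int = 1000
    seed: int = 0
    fallback: float = 5.0

    def validate(self, for_sensitivity: bool = True) -> None:
        if for_sensitivity and (self.delta_grid is None) == (self.A is None):
            raise ValueError(
                "exactly one of 'delta_grid' or 'A' must be provided for a "
                "sensitivity run"
            )
        if self.mode not in ("joint", "per-arm"):
            raise ValueError(f"mode must be 'joint' or 'per-arm', got {self.mode!r}")
        if self.inference not in ("sandwich", "bootstrap", "none"):
            raise ValueError(f"unknown inference method {self.inference!r}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
    return AnalysisConfig(**payload)


def config_hash(cfg) -> str:
    """Stable short hash of a config (dataclass or mapping) for run logs."""
    payload = asdict(cfg) if hasattr(cfg, "__dataclass_fields__") else dict(cfg)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_trial_csv(path: str | Path, config: AnalysisConfig) -> tuple[TrialData, dict]:
    """Load and validate subject-level trial data from a delimited file.

    Enforces 0/1 coding of treatment and outcome and rejects missing values.
    Returns the validated :class:`TrialData` plus a load report (n, arm
    sizes, four-cell counts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (config.treatment, config.outcome, *config.covariates):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}; "
                             f"available: {list(df.columns)}")
    for col in (config.treatment, config.outcome):
        vals = set(pd.unique(df[col].dropna()))
        if not vals <= {0, 1}:
            raise ValueError(
                f"column {col!r} must be coded 0/1, found {sorted(map(str, vals))}; "
                "recode (e.g. yes/no -> 1/0) before loading"
            )
    data = TrialData.from_dataframe(
        df, treatment=config.treatment, outcome=config.outcome,
        covariates=list(config.covariates),
    )
    counts = data.cell_counts()
    report = {
        "n": data.n,
        "arm_sizes": {int(a): int((data.X == a).sum()) for a in (0, 1)},
        "cell_counts": {f"X={x},Y={y}": int(counts.get((x, y), 0))
                        for x in (0, 1) for y in (0, 1)},
    }
    log.info("loaded %s: %s", path.name, report)
    return data, report


def write_results(df: pd.DataFrame, out_prefix: str | Path, meta: dict) -> dict:
    """Write a results table as CSV (full-precision floats) + JSON sidecar.

    The CSV round-trips exactly (repr-precision floats); the sidecar carries
    the run metadata (seed, config hash, guard events) and the same records.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    payload = {"meta": meta, "records": json.loads(df.to_json(orient="records"))}
    json_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    log.info("wrote %s and %s", csv_path, json_path)
    return {"csv": str(csv_path), "json": str(json_path)}
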