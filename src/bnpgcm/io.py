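"""Panel readers/writers, YAML configuration, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dp import GammaPrior
from .sampler import DpmSpec
from .simulate import LongitudinalPanel
from .study import PRECISION_PRIORS, Condition

__all__ = [
    "read_panel",
    "write_panel",
    "load_config",
    "RunManifest",
    "PanelFormatError",
]


class PanelFormatError(ValueError):
    """Raised for malformed or unsupported panel files."""


def write_panel(panel: LongitudinalPanel, path, layout: str = "long") -> None:
    """Write a panel as CSV (long: id,occasion,y,contaminated; wide: id,y1..yT)."""
    path = Path(path)
    if layout == "long":
        panel.to_long_frame().to_csv(path, index=False)
    elif layout == "wide":
        panel.to_wide_frame().to_csv(path, index=False)
    else:
        raise ValueError("layout must be 'long' or 'wide'")


def read_panel(path, layout: str = "long") -> LongitudinalPanel:
    """Read a balanced complete-case panel from CSV.

    Missing cells raise: only balanced complete data are supported.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        required = {"id", "occasion", "y"}
        if not required.issubset(df.columns):
            raise PanelFormatError(f"long panel must have columns {sorted(required)}")
        if df["y"].isna().any():
            raise PanelFormatError("panel contains missing outcome cells")
        if not np.issubdtype(df["y"].dtype, np.number):
            raise PanelFormatError("outcome column must be numeric")
        wide = df.pivot(index="id", columns="occasion", values="y").sort_index()
        if wide.isna().any().any():
            raise PanelFormatError("unbalanced panel: some subject-occasion cells missing")
        codes = np.asarray(sorted(df["occasion"].unique()))
        mask = None
        if "contaminated" in df.columns:
            mask = (
                df.pivot(index="id", columns="occasion", values="contaminated")
                .sort_index()
                .to_numpy(dtype=bool)
            )
        return LongitudinalPanel(
            outcomes=wide.to_numpy(dtype=float),
            occasion_codes=np.arange(len(codes)),
            contamination_mask=mask,
        )
    if layout == "wide":
        ycols = [c for c in df.columns if c.startswith("y")]
        if not ycols or "id" not in df.columns:
            raise PanelFormatError("wide panel must have columns id, y1..yT")
        ycols = sorted(ycols, key=lambda c: int(c[1:]))
        block = df[ycols]
        if block.isna().any().any():
            raise PanelFormatError("panel contains missing outcome cells")
        try:
            y = block.to_numpy(dtype=float)
        except (TypeError, ValueError) as err:
            raise PanelFormatError(f"non-numeric outcome values: {err}") from err
        return LongitudinalPanel(outcomes=y, occasion_codes=np.arange(len(ycols)))
    raise ValueError("layout must be 'long' or 'wide'")


# ---------------------------------------------------------------------------
# configuration

_CONFIG_KEYS = {
    "truncation", "alpha_prior", "base_df", "base_scale_df",
    "fixed_effect_prior_var", "psi_prior_df", "alpha_update",
    "n", "outlier_proportion", "n_replications", "n_iter", "burn_in",
    "base_seed", "sigma2_e", "n_occasions", "beta", "psi", "conditions",
    "outlier", "scale",
}


def _parse_gamma_prior(value) -> GammaPrior:
    if isinstance(value, str):
        try:
            return PRECISION_PRIORS[value]
        except KeyError:
            raise ValueError(
                f"unknown alpha prior label '{value}'; known labels: "
                f"{sorted(PRECISION_PRIORS)}"
            ) from None
    if isinstance(value, dict):
        extra = set(value) - {"shape", "rate"}
        if extra:
            raise ValueError(f"unknown alpha_prior keys: {sorted(extra)}")
        return GammaPrior(float(value["shape"]), float(value["rate"]))
    raise ValueError("alpha_prior must be a label or {shape, rate} mapping")


def load_config(path) -> tuple[DpmSpec, list[Condition]]:
    """Load a YAML study/fit configuration with defaults filled in.

    An empty file yields the standard defaults: truncation C = 50, a
    50,000-iteration chain with half burn-in, 500 replications, the
    population values beta = (6.2, 0.3), sigma2_e = 0.5, Psi =
    diag(1, 0.1), and the four named precision priors available by label
    (noninformative, weak, accurate, inaccurate).
    """
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else None
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    alpha_prior = _parse_gamma_prior(raw.get("alpha_prior", "weak"))
    truncation = int(raw.get("truncation", 50))
    if truncation < 2:
        raise ValueError("truncation must be >= 2")
    spec = DpmSpec(
        truncation=truncation,
        alpha_prior=alpha_prior,
        base_df=raw.get("base_df"),
        base_scale_df=raw.get("base_scale_df"),
        fixed_effect_prior_var=float(raw.get("fixed_effect_prior_var", 1e6)),
        psi_prior_df=float(raw.get("psi_prior_df", 2.0)),
        alpha_update=raw.get("alpha_update", "stick"),
    )

    base_kwargs = dict(
        n=int(raw.get("n", 200)),
        outlier_proportion=float(raw.get("outlier_proportion", 0.0)),
        alpha_prior=alpha_prior,
        n_replications=int(raw.get("n_replications", 500)),
        n_iter=int(raw.get("n_iter", 50_000)),
        burn_in=raw.get("burn_in"),
        base_seed=int(raw.get("base_seed", 0)),
        sigma2_e=float(raw.get("sigma2_e", 0.5)),
        n_occasions=int(raw.get("n_occasions", 4)),
        truncation=truncation,
    )
    conditions = []
    if "conditions" in raw:
        for i, entry in enumerate(raw["conditions"]):
            kw = dict(base_kwargs)
            entry = dict(entry)
            if "alpha_prior" in entry:
                kw["alpha_prior"] = _parse_gamma_prior(entry.pop("alpha_prior"))
            for key in ("n", "outlier_proportion", "n_replications", "n_iter",
                        "burn_in", "base_seed", "label"):
                if key in entry:
                    kw[key] = entry.pop(key)
            if entry:
                raise ValueError(f"unknown condition keys: {sorted(entry)}")
            kw.setdefault("label", f"condition-{i}")
            conditions.append(Condition(**kw))
    else:
        conditions.append(Condition(label="default", **base_kwargs))
    scale = float(raw.get("scale", 1.0))
    if scale != 1.0:
        conditions = [c.scaled(scale) for c in conditions]
    return spec, conditions


# ---------------------------------------------------------------------------
# run manifests

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    version: str = ""
    timings: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _digest(p)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
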