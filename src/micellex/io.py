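"""File formats and run configuration.

Relaxation curves travel as two-column TSV (``time_s<TAB>F`` or
``time_cycles<TAB>F`` with the cycle duration in a JSON sidecar), field
profiles and conformational profiles as headed TSV, reports and manifests as
JSON, and run configuration as nested-key YAML.  All physical outputs carry
units in their headers; computation is done in reduced units (k_B T, sigma,
cycles) with conversion only at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .series import CorrelationSeries

__all__ = [
    "CurveFormatError",
    "read_curve",
    "write_curve",
    "write_calibration_sidecar",
    "read_calibration_sidecar",
    "write_profile_tsv",
    "write_fields_tsv",
    "RunConfig",
    "load_config",
]


class CurveFormatError(ValueError):
    """Malformed curve file; carries the offending line number."""

    def __init__(self, msg: str, line: int | None = None):
        super().__init__(msg if line is None else f"line {line}: {msg}")
        self.line = line


def write_curve(path, series: CorrelationSeries) -> None:
    """Write a relaxation curve as two-column TSV with a domain header."""
    header = "time_s\tF" if series.domain == "seconds" else "time_cycles\tF"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for t, f in zip(series.times, series.F):
            fh.write(f"{float(t)!r}\t{float(f)!r}\n")


def read_curve(path) -> CorrelationSeries:
    """Read a two-column TSV curve; rejects malformed rows with line numbers."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CurveFormatError("empty file")
    head = lines[0].strip().lower().split("\t")
    if head == ["time_s", "f"]:
        domain = "seconds"
    elif head == ["time_cycles", "f"]:
        domain = "cycles"
    else:
        raise CurveFormatError(f"unrecognised header {lines[0]!r}", line=1)
    times, F = [], []
    prev = -np.inf
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise CurveFormatError("expected two tab-separated columns", line=ln)
        try:
            t, f = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveFormatError(f"non-numeric cell in {raw!r}", line=ln) from None
        if not (np.isfinite(t) and np.isfinite(f)):
            raise CurveFormatError("non-finite value", line=ln)
        if t <= prev:
            raise CurveFormatError(f"times not strictly increasing at t={t!r}", line=ln)
        prev = t
        times.append(t)
        F.append(f)
    if len(times) < 2:
        raise CurveFormatError("need at least two data rows")
    return CorrelationSeries(np.array(times), np.array(F), domain=domain)


def write_calibration_sidecar(curve_path, t_cycle: float, extra: dict | None = None) -> Path:
    """JSON sidecar holding the cycle duration for a cycles-domain curve."""
    side = Path(str(curve_path) + ".calibration.json")
    payload = {"t_cycle_s": t_cycle}
    if extra:
        payload.update(extra)
    side.write_text(json.dumps(payload, indent=2))
    return side


def read_calibration_sidecar(curve_path) -> float:
    side = Path(str(curve_path) + ".calibration.json")
    return float(json.loads(side.read_text())["t_cycle_s"])


def write_profile_tsv(path, profile) -> None:
    """Radial profile as TSV: r_mid (sigma), mean, stderr, n."""
    with open(path, "w") as fh:
        fh.write("r_mid_sigma\tmean\tstderr\tn\n")
        for r, m, s, n in zip(profile.r_mid, profile.mean, profile.stderr, profile.counts):
            fh.write(f"{r:.4f}\t{float(m)!r}\t{float(s)!r}\t{n:.1f}\n")


def write_fields_tsv(path, fields, lattice) -> None:
    """Shell fields as TSV: shell index, mid radius and all field profiles."""
    phi_tot = fields.phi_chains() + fields.phi_s
    with open(path, "w") as fh:
        fh.write("shell\tr_mid_sigma\tc_EO\tc_PO\tc_s\tpi\tphi_total\n")
        for j, r in enumerate(lattice.radii):
            fh.write(
                f"{j}\t{r:.4f}\t{float(fields.c_EO[j])!r}\t{float(fields.c_PO[j])!r}"
                f"\t{float(fields.c_s[j])!r}\t{float(fields.pi[j])!r}\t{float(phi_tot[j])!r}\n"
            )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated run configuration (defaults resolved)."""

    chain: dict = dc_field(default_factory=dict)
    potential: dict = dc_field(default_factory=dict)
    lattice: dict = dc_field(default_factory=dict)
    solver: dict = dc_field(default_factory=dict)
    dynamics: dict = dc_field(default_factory=dict)
    fit: dict = dc_field(default_factory=dict)
    output: dict = dc_field(default_factory=dict)
    seed: int | None = None

    _SECTIONS = ("chain", "potential", "lattice", "solver", "dynamics", "fit", "output")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kw = {k: dict(raw.get(k, {})) for k in cls._SECTIONS}
        return cls(seed=raw.get("seed"), **kw)

    def to_yaml(self) -> str:
        data = {k: getattr(self, k) for k in self._SECTIONS if getattr(self, k)}
        if self.seed is not None:
            data["seed"] = self.seed
        return yaml.safe_dump(data, sort_keys=True)

    def chain_spec(self):
        from .chain import CASE_STUDIES, ChainSpec

        c = dict(self.chain)
        if "case" in c:
            return CASE_STUDIES[c["case"]]
        return ChainSpec(**c) if c else CASE_STUDIES["semiflexible"]

    def pair_potential(self):
        from .chain import PairPotential

        return PairPotential(**self.potential) if self.potential else PairPotential()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(raw)
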