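"""Validation report assembly: a JSON-serializable record of every
validation stage plus a human-readable text rendering.

Sections render in fixed order (accuracy, precision, linearity, efficiency,
stability).  Every number in the text summary is taken from the same dict
that serializes to JSON, so the two views cannot drift.  Provenance (seed,
config hash, input digests, package version, timestamp) is isolated in one
block so determinism checks can exclude the timestamp alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from .valstats import (
    ConcordanceResult,
    LinearityResult,
    PrecisionResult,
    StabilityResult,
)

SCHEMA_VERSION = 1

__all__ = ["ValidationReport", "file_digest"]


def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {_key(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return "/".join(str(p) for p in k)
    return str(k)


@dataclass
class ValidationReport:
    accuracy: ConcordanceResult | None = None
    precision_inter: PrecisionResult | None = None
    precision_intra: PrecisionResult | None = None
    linearity: LinearityResult | None = None
    stability: StabilityResult | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def stamp(self, seed: int | None = None, inputs: Mapping[str, str] | None = None,
              config: Mapping[str, Any] | None = None) -> None:
        from . import __version__

        self.provenance["schema_version"] = SCHEMA_VERSION
        self.provenance["package_version"] = __version__
        if seed is not None:
            self.provenance["seed"] = seed
        if inputs:
            self.provenance["input_digests"] = dict(inputs)
        if config is not None:
            blob = json.dumps(_asdict(config), sort_keys=True).encode()
            self.provenance["config_hash"] = "sha256:" + hashlib.sha256(blob).hexdigest()[:16]
        self.provenance["timestamp"] = datetime.now(timezone.utc).isoformat()

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for section in ("accuracy", "precision_inter", "precision_intra",
                        "linearity", "stability"):
            value = getattr(self, section)
            if value is not None:
                out[section] = _asdict(value)
        out["provenance"] = dict(self.provenance)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> dict[str, Any]:
        """Parse a serialized report back to its dict form (round-trip check)."""
        return json.loads(text)

    def render_text(self) -> str:
        d = self.to_dict()
        lines = ["Validation report", "================="]

        def ci(pair: list[float]) -> str:
            return f"(95% CI: {pair[0]:.3g}-{pair[1]:.3g})"

        if "accuracy" in d:
            a = d["accuracy"]
            lines += [
                "",
                "Accuracy",
                f"  Lin concordance: {a['ccc']:.3f} {ci(a['ccc_ci'])}, n={a['n_pairs']}",
                f"  mean difference: {a['mean_diff']:.3g} {ci(a['mean_diff_ci'])}, "
                f"paired-t p={a['t_pvalue']:.3g}",
            ]
        for key, label in (("precision_inter", "Interbatch precision"),
                           ("precision_intra", "Intrabatch precision")):
            if key in d:
                p = d[key]
                lines += [
                    "",
                    label,
                    f"  pooled SD: {p['pooled_sd']:.3g} {ci(p['sd_ci'])} "
                    f"[df convention: {p['df_convention']}, {p['n_groups']} groups]",
                ]
        if "linearity" in d:
            lin = d["linearity"]
            lo, hi = lin["linear_range"]
            lines += ["", "Linearity",
                      f"  linear range: {lo:.3g}-{hi:.3g} ng/uL"]
            if lin.get("score_sd") is not None:
                lines.append(
                    f"  score over range: mean {lin['score_mean']:.2f}, "
                    f"SD {lin['score_sd']:.2f} {ci(lin['score_sd_ci'])}"
                )
            lines += ["", "Amplification efficiency"]
            for gene, fit in lin["per_gene"].items():
                eff = fit["efficiency_pct"]
                eff_s = f"{eff:.1f}%" if eff is not None else "n/a"
                lines.append(
                    f"  {gene}: efficiency {eff_s}, R2 {fit['r2']:.3f}, "
                    f"max |residual| {fit['max_abs_residual']:.2f} Ct"
                )
        if "stability" in d:
            s = d["stability"]
            lines += ["", "Stability",
                      f"  max per-sample SD: {s['max_sd']:.3g} score units"]
            for sample, sd in s["per_sample_sd"].items():
                lines.append(f"  {sample}: SD {sd:.3g}")
        if len(lines) == 2:
            lines.append("\n(no sections)")
        return "\n".join(lines) + "\n"
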