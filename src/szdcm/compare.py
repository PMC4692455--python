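"""Factorial model comparison over volatile parameter classes.

Eight models let different combinations of the inhibitory, excitatory and
endogenous-input parameters fluctuate between epochs.  Models are ranked
by total variational free energy (a lower bound on log model evidence),
reported relative to the null model with no volatile parameters; a margin
of about three nats constitutes strong evidence (odds of roughly 20:1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["enumerate_models", "compare", "ComparisonReport",
           "STRONG_EVIDENCE_NATS"]

STRONG_EVIDENCE_NATS = 3.0

# Row order mirrors the conventional report layout: the full model first,
# then pairs, singles, and the null model last.
_MODEL_ORDER = (
    ("endogenous", "excitatory", "inhibitory"),
    ("excitatory", "inhibitory"),
    ("endogenous", "inhibitory"),
    ("endogenous", "excitatory"),
    ("inhibitory",),
    ("excitatory",),
    ("endogenous",),
    (),
)


def enumerate_models() -> list:
    """All 8 subsets of {inhibitory, excitatory, endogenous}, null included."""
    return [tuple(sorted(m)) for m in _MODEL_ORDER]


def model_name(spec) -> str:
    return " + ".join(sorted(spec)) if spec else "null"


@dataclass
class ComparisonReport:
    models: list                         # model specs in report order
    relative_f: dict                     # name -> F − F(null)
    variance_explained: dict             # name -> fraction
    winner: str
    strong_evidence: bool
    margin_over_null: float
    extras: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"{'model':<40s} {'var expl':>9s} {'rel F':>12s}"]
        for spec in self.models:
            name = model_name(spec)
            flag = " *" if name == self.winner else ""
            lines.append(f"{name:<40s} {self.variance_explained[name]:9.4f} "
                         f"{self.relative_f[name]:12.2f}{flag}")
        lines.append(f"winner: {self.winner} "
                     f"(margin over null {self.margin_over_null:.2f} nats"
                     f"{', strong evidence' if self.strong_evidence else ''})")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        d = {"models": [model_name(m) for m in self.models],
             "relative_free_energy": self.relative_f,
             "variance_explained": self.variance_explained,
             "winner": self.winner, "strong_evidence": self.strong_evidence,
             "margin_over_null": self.margin_over_null}
        Path(path).write_text(json.dumps(d, indent=2))


def compare(results: dict) -> ComparisonReport:
    """Rank inverted models of the same data by total free energy.

    ``results`` maps model spec (tuple of class names) to a Trajectory.
    All trajectories must carry the same data fingerprint; free energies
    are expressed relative to the null model.
    """
    results = {tuple(sorted(k)): v for k, v in results.items()}
    if () not in results:
        raise ValueError("model comparison requires the null model")
    prints = {t.data_fingerprint for t in results.values() if t.data_fingerprint}
    if len(prints) > 1:
        raise ValueError("trajectories were inverted on different data "
                         f"(fingerprints {sorted(prints)})")
    f_null = results[()].total_free_energy
    order = [m for m in enumerate_models() if m in results]
    order += [m for m in sorted(results) if m not in order]
    rel = {model_name(m): results[m].total_free_energy - f_null for m in order}
    ve = {model_name(m): results[m].variance_explained() for m in order}
    winner_spec = max(order, key=lambda m: results[m].total_free_energy)
    winner = model_name(winner_spec)
    margin = results[winner_spec].total_free_energy - f_null
    return ComparisonReport(models=order, relative_f=rel,
                            variance_explained=ve, winner=winner,
                            strong_evidence=bool(margin >= STRONG_EVIDENCE_NATS),
                            margin_over_null=float(margin))
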