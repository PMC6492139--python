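"""Apoptosis-mimicking microstructural change scenarios.

Starting from a baseline tissue, three idealized changes are modelled:

* **shrinkage** — every cell loses a fraction ``v`` of its volume (apoptotic
  volume decrease): the radius scales by ``(1-v)^(1/3)`` and the
  intracellular volume fraction by ``(1-v)``, so the cell density
  ``rho = 3 f_i / (4 pi R^3)`` is conserved.
* **cell_loss** — a fraction ``v`` of the intracellular volume is removed by
  deleting whole cells: ``f_i`` scales by ``(1-v)`` while ``R`` is
  unchanged, so the density drops by the same factor.
* **asynchronous** — only a fraction ``1-p`` of cells shrink while a
  fraction ``p`` remain at the baseline size, giving a bimodal radius
  distribution.  Cell counts are conserved within each subpopulation, so
  ``f_same = p f_i`` and ``f_shrunk = (1-p)(1-v) f_i``.

The default volume decrease ``v = 0.60`` is the largest volume change
observed in vitro for cisplatin-treated cells, i.e. a best case for
detecting the radius change; smaller decreases (0.40, 0.20) are the
standard sweep values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .signal_model import BimodalTissue, Tissue

__all__ = [
    "DEFAULT_VOLUME_DECREASE",
    "V_SWEEP",
    "P_SWEEP",
    "ChangeScenario",
    "apply_shrinkage",
    "apply_cell_loss",
    "apply_asynchronous",
    "density",
]

DEFAULT_VOLUME_DECREASE = 0.60
#: Standard percentage-volume-decrease sweep.
V_SWEEP = (0.60, 0.40, 0.20)
#: Standard same-size-fraction sweep for asynchronous apoptosis.
P_SWEEP = (0.0, 0.25, 0.50, 0.75)

KINDS = ("shrinkage", "cell_loss", "asynchronous")


def _check_v(v: float) -> None:
    if not 0 < v < 1:
        raise ValueError(f"volume decrease v must be in (0, 1), got {v}")


def apply_shrinkage(baseline: Tissue, v: float = DEFAULT_VOLUME_DECREASE) -> Tissue:
    """All cells lose a fraction ``v`` of their volume; density conserved.

    R' = (1-v)^(1/3) R and f_i' = (1-v) f_i; diffusivities and T2 unchanged.
    """
    _check_v(v)
    return Tissue(
        R=(1.0 - v) ** (1.0 / 3.0) * baseline.R,
        f_i=(1.0 - v) * baseline.f_i,
        D_i=baseline.D_i,
        D_e=baseline.D_e,
        T2=baseline.T2,
    )


def apply_cell_loss(baseline: Tissue, v: float = DEFAULT_VOLUME_DECREASE) -> Tissue:
    """A fraction ``v`` of cells disappear: f_i' = (1-v) f_i, R unchanged."""
    _check_v(v)
    return Tissue(
        R=baseline.R,
        f_i=(1.0 - v) * baseline.f_i,
        D_i=baseline.D_i,
        D_e=baseline.D_e,
        T2=baseline.T2,
    )


def apply_asynchronous(
    baseline: Tissue, v: float = DEFAULT_VOLUME_DECREASE, p: float = 0.5
) -> BimodalTissue:
    """A fraction ``p`` of cells keep the baseline size, the rest shrink.

    Cell counts are conserved within each subpopulation, so the total
    restricted fraction becomes ``f_i (p + (1-p)(1-v))``.
    """
    _check_v(v)
    if not 0 <= p <= 1:
        raise ValueError(f"same-size fraction p must be in [0, 1], got {p}")
    return BimodalTissue(
        R_same=baseline.R,
        R_shrunk=(1.0 - v) ** (1.0 / 3.0) * baseline.R,
        f_same=p * baseline.f_i,
        f_shrunk=(1.0 - p) * (1.0 - v) * baseline.f_i,
        D_i=baseline.D_i,
        D_e=baseline.D_e,
        T2=baseline.T2,
    )


def density(t: Tissue) -> float:
    """Cell density rho = 3 f_i / (4 pi R^3), cells per um^3."""
    return 3.0 * t.f_i / (4.0 * math.pi * t.R**3)


@dataclass(frozen=True)
class ChangeScenario:
    """A baseline tissue plus one derived change state.

    ``changed`` is a :class:`Tissue` for the synchronous kinds and a
    :class:`BimodalTissue` for the asynchronous kind.  ``delta`` gives the
    magnitude of the single-radius-model parameter changes |p2 - p1| used by
    the detection threshold; for the asynchronous kind the reference change
    in R is still the full shrinkage (the biologically relevant decrease),
    while the f_i change refers to the total restricted fraction.
    """

    baseline: Tissue
    kind: str
    v: float = DEFAULT_VOLUME_DECREASE
    p: float = 0.0
    changed: Tissue | BimodalTissue = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "shrinkage":
            changed = apply_shrinkage(self.baseline, self.v)
        elif self.kind == "cell_loss":
            changed = apply_cell_loss(self.baseline, self.v)
        else:
            changed = apply_asynchronous(self.baseline, self.v, self.p)
        object.__setattr__(self, "changed", changed)

    @property
    def delta(self) -> dict[str, float]:
        """Magnitudes of the parameter changes |p2 - p1| for R and f_i."""
        if self.kind == "shrinkage":
            return {
                "R": self.baseline.R - self.changed.R,
                "f_i": self.baseline.f_i - self.changed.f_i,
            }
        if self.kind == "cell_loss":
            return {"R": 0.0, "f_i": self.baseline.f_i - self.changed.f_i}
        # asynchronous: R change of the shrinking population; f_i change of
        # the total restricted fraction
        return {
            "R": self.baseline.R - self.changed.R_shrunk,
            "f_i": self.baseline.f_i - self.changed.f_total,
        }
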