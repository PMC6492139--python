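"""Named acquisition protocols and protocol file I/O.

A protocol is a tuple of :class:`~dwires.signal_model.Measurement`.  The six
named four-measurement protocols are published PGSE acquisitions: three
D-optimized designs (``D-opt_300``, ``D-opt_80``, ``D-opt_60``, the subscript
being the maximum gradient strength in mT/m) and three non-optimized
AxCaliber-style {G, Delta} grids matched on maximum gradient and b-value
(``Non-opt_300``, ``Non-opt_80``, ``Non-opt_60``).  Echo times are the
minimum feasible, TE = Delta + delta + T_c, capped at 100 ms.

The four-b-value clinical ADC protocol (b = 150/300/500/800 s/mm^2 at fixed
timing) is also provided for ADC demonstrations.

Protocol files are plain delimited text with columns
``G_mT_per_m, Delta_ms, delta_ms, TE_ms``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .signal_model import Measurement

__all__ = [
    "PROTOCOLS",
    "CLINICAL_ADC_PROTOCOL",
    "get_protocol",
    "read_protocol",
    "write_protocol",
]


def _protocol(gs, Deltas, deltas) -> tuple[Measurement, ...]:
    return tuple(
        Measurement(G=g, Delta=D, delta=d) for g, D, d in zip(gs, Deltas, deltas)
    )


PROTOCOLS: dict[str, tuple[Measurement, ...]] = {
    "D-opt_300": _protocol(
        (56.4, 38.9, 297.0, 109.0),
        (23.2, 62.2, 16.3, 82.7),
        (10.6, 24.8, 4.28, 4.22),
    ),
    "D-opt_80": _protocol(
        (43.1, 44.9, 80.0, 80.0),
        (65.2, 77.3, 26.1, 19.3),
        (21.7, 9.72, 14.1, 7.25),
    ),
    "D-opt_60": _protocol(
        (35.9, 36.2, 60.0, 60.0),
        (59.4, 27.3, 79.2, 29.6),
        (27.6, 15.3, 7.85, 17.6),
    ),
    "Non-opt_300": _protocol(
        (150.0, 150.0, 300.0, 300.0),
        (80.0, 20.0, 80.0, 20.0),
        (2.65, 2.65, 2.65, 2.65),
    ),
    "Non-opt_80": _protocol(
        (40.0, 40.0, 80.0, 80.0),
        (80.0, 20.0, 80.0, 20.0),
        (10.2, 10.2, 10.2, 10.2),
    ),
    "Non-opt_60": _protocol(
        (30.0, 30.0, 60.0, 60.0),
        (80.0, 20.0, 80.0, 20.0),
        (13.5, 13.5, 13.5, 13.5),
    ),
}

#: Multi-b-value clinical ADC acquisition: b ~ 150/300/500/800 s/mm^2.
CLINICAL_ADC_PROTOCOL: tuple[Measurement, ...] = _protocol(
    (13.2, 18.6, 24.0, 30.4),
    (32.0, 32.0, 32.0, 32.0),
    (22.2, 22.2, 22.2, 22.2),
)


def get_protocol(name: str) -> tuple[Measurement, ...]:
    """Look up a named protocol; raises KeyError with the known names."""
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; known: {sorted(PROTOCOLS)}"
        ) from None


def write_protocol(path: str | Path, protocol: Iterable[Measurement]) -> None:
    """Write a protocol as delimited text (CSV)."""
    rows = [
        {"G_mT_per_m": m.G, "Delta_ms": m.Delta, "delta_ms": m.delta, "TE_ms": m.TE}
        for m in protocol
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_protocol(path: str | Path) -> tuple[Measurement, ...]:
    """Read a protocol file written by :func:`write_protocol`."""
    df = pd.read_csv(path)
    required = {"G_mT_per_m", "Delta_ms", "delta_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"protocol file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        te = float(row["TE_ms"]) if "TE_ms" in df.columns else None
        out.append(
            Measurement(
                G=float(row["G_mT_per_m"]),
                Delta=float(row["Delta_ms"]),
                delta=float(row["delta_ms"]),
                TE=te,
            )
        )
    return tuple(out)
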