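"""Polymer parameter presets (persistence length and monomer size).

Literature values, in nanometers, for common synthetic polymers,
polyelectrolytes at high salt, and biofilaments, together with helpers to
regenerate the chemisorption length-scale table (``s0``, ``S*``) from
them.  Hyaluronan is reported with two persistence-length ranges in the
literature (possibly reflecting association phenomena); each range is
shipped as its own preset carrying the midpoint value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from semiflex.adsorption import chemisorption_scales

__all__ = ["PolymerPreset", "load_presets", "get_preset", "table2_report"]


@dataclass(frozen=True)
class PolymerPreset:
    """A named (ell, b) pair in nanometers.

    ``ratio_printed`` is the aspect ratio ell/b as usually quoted;
    ``ratio_consistent`` records whether that quote matches ell/b within
    rounding (it does for all presets except PDADMAC, whose quoted ratio
    is inconsistent with its quoted ell and b).
    """

    name: str
    ell: float  # nm
    b: float  # nm
    ratio_printed: float
    ratio_consistent: bool = True

    @property
    def ratio(self) -> float:
        return self.ell / self.b


_PRESETS = [
    PolymerPreset("PE (dodecanol)", 0.59, 0.13, 4.5),
    PolymerPreset("PIB (benzene)", 0.59, 0.26, 2.3),
    PolymerPreset("PS (cyclohexane)", 0.86, 0.26, 3.3),
    PolymerPreset("PDMS (hexane)", 0.57, 0.29, 2.0),
    PolymerPreset("NaPSS (high salt)", 1.0, 0.25, 4.0),
    PolymerPreset("PDADMAC (high salt)", 3.0, 0.47, 5.3, ratio_consistent=False),
    PolymerPreset("HA (high salt, low)", 4.5, 1.0, 4.5),
    PolymerPreset("HA (high salt, high)", 8.5, 1.0, 8.5),
    PolymerPreset("d-DNA", 50.0, 0.34, 150.0),
    PolymerPreset("IF", 1.0e3, 10.0, 100.0),
    PolymerPreset("F-actin", 17.0e3, 5.0, 3400.0),
]


def load_presets() -> list[PolymerPreset]:
    """All shipped presets (aspect ratios recomputed from ell and b)."""
    return list(_PRESETS)


def get_preset(name: str) -> PolymerPreset:
    """Look up a preset by (case-insensitive) name prefix."""
    low = name.lower()
    matches = [p for p in _PRESETS if p.name.lower().startswith(low)]
    if not matches:
        raise KeyError(f"no preset matching {name!r}")
    if len(matches) > 1:
        raise KeyError(
            f"ambiguous preset {name!r}: " + ", ".join(p.name for p in matches)
        )
    return matches[0]


def table2_report() -> pd.DataFrame:
    """Chemisorption length scales for every preset.

    Columns: name, ell (nm), b (nm), s0 (nm), S_star (nm) with
    ``s0 = (ell b^2)^(1/3)`` and ``S* = ell^(5/3) b^(-2/3)`` (unit
    prefactors).
    """
    rows = []
    for p in load_presets():
        s0, S_star = chemisorption_scales(p.ell, p.b)
        rows.append(
            {"name": p.name, "ell": p.ell, "b": p.b, "s0": s0, "S_star": S_star}
        )
    return pd.DataFrame(rows)
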