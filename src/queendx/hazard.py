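"""Cumulative pesticide hazard quotients (HQ) and mixture formulation.

A component's hazard quotient is its concentration in the matrix (ppb)
divided by the honey bee LD50 (µg/bee, adult worker oral convention); the
cumulative HQ of a mixture is the plain additive sum over components.  This
additive framework standardises mixture doses even though real xenobiotic
interactions need not be additive, and the worker-oral LD50 convention is
kept unchanged for queen topical exposures (no correction factor exists).

``formulate_mixture`` inverts the calculation: given field-realistic
relative concentrations and LD50s, it scales all components by a single
factor so the mixture hits a requested cumulative HQ — the way a ~511-HQ
cocktail is blended from median wax detection levels.

Display convention: contributing HQs round to 2 decimals, totals to the
nearest integer; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

VALID_GROUPS = {"acaricide", "fungicide", "herbicide", "insecticide", "metabolite"}


def component_hq(concentration_ppb: float, ld50_ug_per_bee: float) -> float:
    """Hazard quotient of one component: concentration (ppb) / LD50 (µg/bee)."""
    if concentration_ppb <= 0:
        raise ValueError("concentration_ppb must be positive")
    if ld50_ug_per_bee <= 0:
        raise ValueError("ld50_ug_per_bee must be positive")
    return concentration_ppb / ld50_ug_per_bee


@dataclass(frozen=True)
class PesticideComponent:
    """One compound of a pesticide mixture."""

    name: str
    concentration_ppb: float
    ld50_ug_per_bee: float
    mode_of_action: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        component_hq(self.concentration_ppb, self.ld50_ug_per_bee)  # validates
        if self.group and self.group not in VALID_GROUPS:
            raise ValueError(
                f"{self.name}: group {self.group!r} not in {sorted(VALID_GROUPS)}"
            )

    @property
    def contributing_hq(self) -> float:
        return component_hq(self.concentration_ppb, self.ld50_ug_per_bee)


@dataclass(frozen=True)
class MixtureSpec:
    """A pesticide cocktail and its cumulative hazard quotient."""

    components: tuple[PesticideComponent, ...]
    solvent: str = "acetone"

    @property
    def total_hq(self) -> float:
        return total_hq(self.components)

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped view with display rounding (2 dp per component,
        integer total); full precision stays on the objects."""
        rows = [
            {
                "name": c.name,
                "mode_of_action": c.mode_of_action,
                "group": c.group,
                "concentration_ppb": c.concentration_ppb,
                "ld50_ug_per_bee": c.ld50_ug_per_bee,
                "contributing_hq": round(c.contributing_hq, 2),
            }
            for c in self.components
        ]
        df = pd.DataFrame(rows)
        df.attrs["total_hq"] = round(self.total_hq)
        return df


def total_hq(components: Iterable[PesticideComponent]) -> float:
    """Cumulative hazard quotient: the additive sum of contributing HQs."""
    return float(sum(c.contributing_hq for c in components))


def formulate_mixture(
    profile: Mapping[str, float],
    ld50s: Mapping[str, float],
    desired_total_hq: float,
    modes: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
    solvent: str = "acetone",
) -> MixtureSpec:
    """Scale a relative concentration *profile* to a requested cumulative HQ.

    *profile* maps compound name → relative ppb (zero-proportion compounds
    are omitted); all retained compounds need an LD50.  One common factor
    scales every concentration so the mixture's total HQ equals
    *desired_total_hq* (exactly, up to floating point).
    """
    if desired_total_hq <= 0:
        raise ValueError("desired_total_hq must be positive")
    active = {name: rel for name, rel in profile.items() if rel != 0}
    if not active:
        raise ValueError("profile has no non-zero components")
    if any(rel < 0 for rel in active.values()):
        raise ValueError("relative concentrations must be non-negative")
    missing = sorted(set(active) - set(ld50s))
    if missing:
        raise ValueError(f"missing LD50 for compounds: {missing}")

    unit_hq = sum(rel / ld50s[name] for name, rel in active.items())
    scale = desired_total_hq / unit_hq
    components = tuple(
        PesticideComponent(
            name=name,
            concentration_ppb=rel * scale,
            ld50_ug_per_bee=ld50s[name],
            mode_of_action=(modes or {}).get(name, ""),
            group=(groups or {}).get(name, ""),
        )
        for name, rel in active.items()
    )
    return MixtureSpec(components=components, solvent=solvent)


def load_cocktail_fixture() -> tuple[MixtureSpec, pd.DataFrame]:
    """The nine-component reference cocktail shipped with the package.

    Concentrations are the published target levels of the ~511-HQ blend
    (field-realistic proportions of wax-detected compounds); LD50s are
    back-computed as concentration / published contributing quotient, since
    the source table prints quotients rather than LD50s.  Returns the
    mixture plus the raw table (including the published quotient column).
    """
    with resources.files("queendx").joinpath("data/cocktail_mixture.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    components = tuple(
        PesticideComponent(
            name=row["name"],
            concentration_ppb=float(row["concentration_ppb"]),
            ld50_ug_per_bee=float(row["concentration_ppb"]) / float(row["published_hq"]),
            mode_of_action=row["mode_of_action"],
            group=row["group"],
        )
        for _, row in table.iterrows()
    )
    return MixtureSpec(components=components), table
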