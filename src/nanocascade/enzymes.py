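"""Enzyme kinetic parameters and definitions.

The package ships a default enzyme table (``data/enzymes.toml``) covering the
saccharification and glycolytic enzymes used throughout: apparent
Michaelis-Menten constants measured free in solution and as displayed on
quantum dots, the oligomeric state of each enzyme, monomer molecular weight,
and the estimated range of copies that can self-assemble per nanoparticle
type.

Conventions
-----------
* ``kcat`` is the turnover number per monomer (active site), in s^-1.
* ``km`` is in micromolar.
* Enzyme concentrations elsewhere in the package refer to the holoenzyme;
  the catalytically competent site concentration is ``subunits`` times that.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

__all__ = ["MMParams", "EnzymeDef", "load_enzyme_table", "default_enzyme_table"]


class MMParams(BaseModel):
    """Michaelis-Menten parameters for one enzyme in one context.

    Attributes
    ----------
    kcat : float
        Turnover number per monomer, s^-1. Must be positive.
    km : float
        Michaelis constant, uM. Must be positive.
    direction_note : str
        Free-text note, e.g. when constants were measured in the direction
        opposite to the cascade flux.
    """

    kcat: float = Field(gt=0)
    km: float = Field(gt=0)
    direction_note: str = ""

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/KM in mM^-1 s^-1."""
        return self.kcat / self.km * 1e3


class EnzymeDef(BaseModel):
    """One enzyme: identity, oligomeric state, kinetics, and NP capacity."""

    name: str
    abbreviation: str
    subunits: int
    monomer_mw: float = Field(gt=0, description="monomer molecular weight, kDa")
    params_free: MMParams
    params_bound: MMParams | None = None
    capacity: dict[str, tuple[int, int]] = Field(default_factory=dict)
    delta_g: float | None = Field(
        default=None, description="standard transformed reaction energy, kJ/mol"
    )

    @field_validator("subunits")
    @classmethod
    def _subunits_allowed(cls, v: int) -> int:
        if v not in (1, 2, 4):
            raise ValueError(f"subunits must be 1, 2 or 4, got {v}")
        return v

    @field_validator("capacity")
    @classmethod
    def _capacity_ordered(cls, v):
        for np_name, (lo, hi) in v.items():
            if lo > hi:
                raise ValueError(f"capacity min > max for {np_name}: ({lo}, {hi})")
        return v

    def params(self, context: str) -> MMParams:
        """Kinetic parameters for ``context`` ('free' or 'bound')."""
        if context == "free":
            return self.params_free
        if context == "bound":
            if self.params_bound is None:
                raise ValueError(f"{self.abbreviation}: no bound-context parameters")
            return self.params_bound
        raise ValueError(f"unknown context {context!r}")

    @property
    def oligomer_mw(self) -> float:
        """Holoenzyme molecular weight, kDa."""
        return self.subunits * self.monomer_mw


def _parse_table(raw: dict) -> dict[str, EnzymeDef]:
    table = {}
    for abbrev, entry in raw.items():
        bound = entry.get("bound")
        table[abbrev] = EnzymeDef(
            name=entry["name"],
            abbreviation=abbrev,
            subunits=entry["subunits"],
            monomer_mw=entry["monomer_mw"],
            params_free=MMParams(**entry["free"]),
            params_bound=MMParams(**bound) if bound else None,
            capacity={k: tuple(v) for k, v in entry.get("capacity", {}).items()},
            delta_g=entry.get("delta_g"),
        )
    return table


def load_enzyme_table(path: str | Path) -> dict[str, EnzymeDef]:
    """Load an enzyme table from a TOML file keyed by enzyme abbreviation."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return _parse_table(raw)


def default_enzyme_table() -> dict[str, EnzymeDef]:
    """The packaged default enzyme table."""
    data = resources.files("nanocascade").joinpath("data/enzymes.toml").read_bytes()
    return _parse_table(tomllib.loads(data.decode()))
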