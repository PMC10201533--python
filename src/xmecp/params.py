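"""Element parameters for the extended-Hueckel engine.

The shipped table (``data/eht_params.yaml``) carries, per element, the valence
shells with Slater exponents and valence-state ionization energies (the
on-site matrix elements H_mumu, in hartree), plus the two global constants of
the pairwise Born-Mayer repulsion.  A custom table can be loaded by path for
experimentation; the file format is versioned.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Shell", "ElementParams", "ParameterTable", "load_table", "get_default_table"]


@dataclass(frozen=True)
class Shell:
    n: int
    l: str          # "s" or "p"
    zeta: float     # Slater exponent, a.u.
    h_onsite: float  # on-site energy, hartree (negative)

    def __post_init__(self) -> None:
        if self.l not in ("s", "p"):
            raise ValueError(f"unsupported angular momentum {self.l!r}")
        if self.zeta <= 0:
            raise ValueError("Slater exponent must be positive")
        if self.h_onsite >= 0:
            raise ValueError("on-site energy must be negative")


@dataclass(frozen=True)
class ElementParams:
    symbol: str
    valence_electrons: int
    shells: tuple[Shell, ...]
    r_cov: float = 0.0  # covalent radius, bohr (short-range bond well center)

    def __post_init__(self) -> None:
        if self.valence_electrons < 1:
            raise ValueError("valence electron count must be >= 1")

    @property
    def n_functions(self) -> int:
        return sum(1 if sh.l == "s" else 3 for sh in self.shells)


class ParameterTable:
    """Mapping element symbol -> :class:`ElementParams` plus global constants."""

    def __init__(
        self,
        elements: dict[str, ElementParams],
        repulsion_b: float,
        repulsion_c: float,
        srb_depth: float = 0.0,
        srb_width: float = 3.0,
        wolfsberg_helmholz: float = 1.75,
        version: int = 1,
    ):
        self._elements = dict(elements)
        self.repulsion_b = repulsion_b
        self.repulsion_c = repulsion_c
        self.srb_depth = srb_depth
        self.srb_width = srb_width
        self.wolfsberg_helmholz = wolfsberg_helmholz
        self.version = version

    def __getitem__(self, symbol: str) -> ElementParams:
        try:
            return self._elements[symbol.capitalize()]
        except KeyError:
            raise KeyError(f"element {symbol!r} not parametrized") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.capitalize() in self._elements

    def __iter__(self):
        return iter(self._elements)


def load_table(path: str | Path) -> ParameterTable:
    """Load a parameter table from a YAML file (see the shipped data file)."""
    data = yaml.safe_load(Path(path).read_text())
    elements = {}
    for sym, rec in data["elements"].items():
        shells = tuple(
            Shell(n=s["n"], l=s["l"], zeta=float(s["zeta"]), h_onsite=float(s["h_onsite"]))
            for s in rec["shells"]
        )
        elements[sym] = ElementParams(
            symbol=sym,
            valence_electrons=int(rec["valence_electrons"]),
            shells=shells,
            r_cov=float(rec.get("r_cov", 0.0)),
        )
    rep = data["repulsion"]
    srb = data.get("srb", {})
    return ParameterTable(
        elements,
        repulsion_b=float(rep["b"]),
        repulsion_c=float(rep["c"]),
        srb_depth=float(srb.get("d", 0.0)),
        srb_width=float(srb.get("beta", 3.0)),
        wolfsberg_helmholz=float(data.get("wolfsberg_helmholz", 1.75)),
        version=int(data.get("version", 1)),
    )


_DEFAULT: ParameterTable | None = None


def get_default_table() -> ParameterTable:
    """The shipped parameter table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("xmecp").joinpath("data/eht_params.yaml")
        ) as p:
            _DEFAULT = load_table(p)
    return _DEFAULT
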