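"""Mass constants for fragment-ion arithmetic.

All masses are monoisotopic and expressed in Dalton. The defaults can be
overridden (e.g. to swap in an average-mass table) either programmatically
or from a plain-text ``key: value`` config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from pyteomics import mass as _pt_mass

#: The twenty canonical amino-acid letters, in alphabetical order.
CANONICAL_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residues whose side chains carry high proton affinity (basic sites).
BASIC_RESIDUES: frozenset[str] = frozenset("KRH")

_DEFAULT_RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic masses used by all fragment-relation predicates.

    Attributes
    ----------
    proton : float
        Mass of a proton (charge carrier), Da.
    h2o, nh3, co, nh : float
        Neutral-loss masses, Da. Water and ammonia losses are common for
        b/y ions; CO loss converts a b ion into an a ion; NH loss covers
        the remaining small-neutral channel.
    residue_masses : dict
        Monoisotopic residue (amino-acid minus water) masses for the 20
        canonical letters.
    basic_residues : frozenset
        Residues counted as basic sites (K, R, H).
    """

    proton: float = 1.00728
    h2o: float = 18.01056
    nh3: float = 17.02655
    co: float = 27.99491
    nh: float = 15.01090
    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RESIDUE_MASSES)
    )
    basic_residues: frozenset[str] = BASIC_RESIDUES

    def __post_init__(self) -> None:
        for name in ("proton", "h2o", "nh3", "co", "nh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"mass constant {name!r} must be positive")
        if len(self.residue_masses) != 20:
            raise ValueError(
                f"residue_masses must have exactly 20 entries, "
                f"got {len(self.residue_masses)}"
            )
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("all residue masses must be positive")

    @property
    def neutral_losses(self) -> dict[str, float]:
        """Single neutral-loss masses, in the fixed order they are tried."""
        return {"h2o": self.h2o, "nh3": self.nh3, "co": self.co, "nh": self.nh}

    def residue_mass_sum(self, sequence: str) -> float:
        """Sum of residue masses for ``sequence``; KeyError-free wrapper."""
        try:
            return sum(self.residue_masses[aa] for aa in sequence)
        except KeyError as exc:
            raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None

    def peptide_mass(self, sequence: str) -> float:
        """Neutral monoisotopic peptide mass: residue sum plus one water."""
        return self.residue_mass_sum(sequence) + self.h2o

    @classmethod
    def from_config(cls, path: str | Path) -> "MassConstants":
        """Load overrides from a ``key: value`` text file.

        Keys may be any of the scalar constants or single residue letters.
        Unlisted values keep their defaults.
        """
        overrides: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = line.split(":", 1)
                overrides[key.strip()] = float(value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        base = cls()
        scalars = {k: v for k, v in overrides.items() if k in ("proton", "h2o", "nh3", "co", "nh")}
        residues = dict(base.residue_masses)
        for k, v in overrides.items():
            if k in scalars:
                continue
            if k not in residues:
                raise ValueError(f"unknown constant {k!r} in {path}")
            residues[k] = v
        return replace(base, residue_masses=residues, **scalars)


DEFAULT_CONSTANTS = MassConstants()
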