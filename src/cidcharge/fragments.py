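"""Mass-arithmetic relations between fragment peaks under charge hypotheses.

The physics in one paragraph: CID cleavage of a peptide of neutral mass M
at one backbone bond yields an N-terminal b ion and a C-terminal y ion.
At charge +1 their m/z values are ``sum(prefix residues) + proton`` and
``sum(suffix residues) + H2O + proton``, so a complementary (+1, +1) pair
satisfies ``m1 + m2 = M + 2*proton``. Writing M in terms of the precursor
m/z ``mp`` under a charge hypothesis z (``M = z*mp - z*proton``) gives
observable identities that hold without knowing the sequence:

* (+1, +1) pair:  ``m1 + m2 = 2*mp``          (z = 2)
                  ``m1 + m2 = 3*mp - proton`` (z = 3)
* (+1, +2) pair, the +2 member at m2:
                  ``m1 + 2*m2 = 2*mp + proton`` (z = 2)
                  ``m1 + 2*m2 = 3*mp``          (z = 3)

(symmetrically with the +2 member at m1). A +2 fragment at m also implies
a +1 counterpart at ``2*m - proton``. These identities, tested within an
absolute tolerance window and optionally with single neutral losses (H2O,
NH3, CO, NH) added back to one pair member, are the substrate for every
charge-state feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import MassConstants, DEFAULT_CONSTANTS
from .spectra import Spectrum

RelationKind = Literal["CP11", "CP12_LOW2", "CP12_HIGH2"]

#: All relation kinds, in enumeration order.
RELATION_KINDS: tuple[RelationKind, ...] = ("CP11", "CP12_LOW2", "CP12_HIGH2")


@dataclass(frozen=True)
class Tolerance:
    """Symmetric absolute mass-match window, Da. Ion-trap default 0.5."""

    tol: float = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class PairRelation:
    """One matched relation between peaks ``i < j`` (m/z order).

    ``loss_applied`` is ``None`` for a direct match, else a tuple
    ``(member, loss)`` with member ``"low"``/``"high"`` naming the peak the
    neutral loss was added back to.
    """

    i: int
    j: int
    kind: RelationKind
    charge_hypothesis: int
    loss_applied: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("relation members must satisfy i < j in m/z order")
        if self.kind not in RELATION_KINDS:
            raise ValueError(f"unknown relation kind {self.kind!r}")
        if self.charge_hypothesis not in (2, 3):
            raise ValueError("charge hypothesis must be 2 or 3")


def by_ion_mz(
    residues: str | Sequence[float],
    terminal: Literal["N", "C"],
    charge: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Theoretical m/z of a b ion (N-terminal) or y ion (C-terminal).

    ``residues`` is either a sequence of residue masses or a string of
    residue letters (the prefix for b ions, the suffix for y ions). The
    neutral y fragment keeps the C-terminal water, so its +1 ion carries
    water plus a proton on top of the residue sum.
    """
    if charge not in (1, 2):
        raise ValueError("fragment charge must be 1 or 2")
    if terminal not in ("N", "C"):
        raise ValueError("terminal must be 'N' or 'C'")
    if isinstance(residues, str):
        residue_sum = constants.residue_mass_sum(residues)
    else:
        residue_sum = float(np.sum(residues))
    if residue_sum <= 0:
        raise ValueError("residue list must be non-empty")
    singly = residue_sum + constants.proton
    if terminal == "C":
        singly += constants.h2o
    if charge == 1:
        return singly
    return (singly + constants.proton) / 2.0


def cp11_target(mp: float, z: int, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Expected m1 + m2 for a (+1, +1) complementary pair under charge z."""
    if z == 2:
        return 2.0 * mp
    if z == 3:
        return 3.0 * mp - constants.proton
    raise ValueError("charge hypothesis must be 2 or 3")


def cp12_target(mp: float, z: int, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Expected (+1 m/z) + 2*(+2 m/z) for a (+1, +2) pair under charge z."""
    if z == 2:
        return 2.0 * mp + constants.proton
    if z == 3:
        return 3.0 * mp
    raise ValueError("charge hypothesis must be 2 or 3")


def is_cp11(
    m1: float,
    m2: float,
    mp: float,
    z: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
) -> bool:
    """Is (m1, m2) mass-consistent with a (+1, +1) complementary pair?"""
    if not m1 < m2:
        raise ValueError("require m1 < m2")
    return abs(m1 + m2 - cp11_target(mp, z, constants)) <= tolerance.tol


def is_cp12(
    m1: float,
    m2: float,
    mp: float,
    z: int,
    which_is_2: Literal["low", "high"],
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
) -> bool:
    """Is (m1, m2) consistent with a (+1, +2) pair, the named member +2?"""
    if not m1 < m2:
        raise ValueError("require m1 < m2")
    target = cp12_target(mp, z, constants)
    if which_is_2 == "low":
        value = 2.0 * m1 + m2
    elif which_is_2 == "high":
        value = m1 + 2.0 * m2
    else:
        raise ValueError("which_is_2 must be 'low' or 'high'")
    return abs(value - target) <= tolerance.tol


# ---------------------------------------------------------------------------
# Vectorized pair masks (upper-triangle i < j in m/z order)
# ---------------------------------------------------------------------------

def _loss_values(constants: MassConstants) -> np.ndarray:
    return np.array(list(constants.neutral_losses.values()))


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _match_any(values: np.ndarray, target: float, tol: float, shifts: np.ndarray) -> np.ndarray:
    """True where |values + shift - target| <= tol for any shift."""
    return np.any(np.abs(values[:, None] + shifts[None, :] - target) <= tol, axis=1)


def _relation_masks(
    mz: np.ndarray,
    mp: float,
    constants: MassConstants,
    tolerance: Tolerance,
    losses_enabled: bool,
) -> dict[tuple[RelationKind, int], np.ndarray]:
    """Boolean match mask per (kind, z) over all pairs i < j.

    A neutral loss added back to a member shifts the tested linear form by
    the loss mass times the member's coefficient (1 for a +1 slot, 2 for
    the +2 slot), so losses reduce to a set of scalar shifts.
    """
    n = mz.size
    ii, jj = _pair_indices(n)
    losses = _loss_values(constants)
    if losses_enabled:
        shift_1 = np.concatenate([[0.0], losses])             # coefficient-1 members only
        shift_12 = np.concatenate([[0.0], losses, 2.0 * losses])  # either coefficient
    else:
        shift_1 = shift_12 = np.zeros(1)
    s_sum = mz[ii] + mz[jj]
    s_low2 = 2.0 * mz[ii] + mz[jj]
    s_high2 = mz[ii] + 2.0 * mz[jj]
    masks: dict[tuple[RelationKind, int], np.ndarray] = {}
    for z in (2, 3):
        masks[("CP11", z)] = _match_any(s_sum, cp11_target(mp, z, constants), tolerance.tol, shift_1)
        t12 = cp12_target(mp, z, constants)
        masks[("CP12_LOW2", z)] = _match_any(s_low2, t12, tolerance.tol, shift_12)
        masks[("CP12_HIGH2", z)] = _match_any(s_high2, t12, tolerance.tol, shift_12)
    return masks


def pair_relation_masks(
    spectrum: Spectrum,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
    losses_enabled: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[RelationKind, int], np.ndarray]]:
    """Pair index arrays (i, j) and the per-(kind, z) match masks."""
    ii, jj = _pair_indices(len(spectrum))
    return ii, jj, _relation_masks(spectrum.mz, spectrum.precursor_mz, constants, tolerance, losses_enabled)


def _first_matching_loss(
    expr_base: float,
    coeff_low: float,
    coeff_high: float,
    target: float,
    tol: float,
    constants: MassConstants,
    losses_enabled: bool,
) -> tuple[bool, tuple[str, str] | None]:
    """Try no-loss, then each loss on the low member, then on the high."""
    if abs(expr_base - target) <= tol:
        return True, None
    if losses_enabled:
        for member, coeff in (("low", coeff_low), ("high", coeff_high)):
            for name, mass in constants.neutral_losses.items():
                if abs(expr_base + coeff * mass - target) <= tol:
                    return True, (member, name)
    return False, None


def enumerate_pair_relations(
    spectrum: Spectrum,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
    losses_enabled: bool = True,
) -> list[PairRelation]:
    """All pair relations in a spectrum, under both charge hypotheses.

    Each (i, j, kind, z) combination appears at most once; when neutral
    losses are enabled the direct match is tried first, then each single
    loss on the lower-m/z member, then on the higher-m/z member.
    """
    n = len(spectrum)
    if n < 2:
        return []
    mz = spectrum.mz
    mp = spectrum.precursor_mz
    ii, jj, masks = pair_relation_masks(spectrum, constants, tolerance, losses_enabled)
    relations: list[PairRelation] = []
    coeffs = {"CP11": (1.0, 1.0), "CP12_LOW2": (2.0, 1.0), "CP12_HIGH2": (1.0, 2.0)}
    for kind in RELATION_KINDS:
        c_low, c_high = coeffs[kind]
        for z in (2, 3):
            target = (cp11_target if kind == "CP11" else cp12_target)(mp, z, constants)
            hits = np.nonzero(masks[(kind, z)])[0]
            for p in hits:
                i, j = int(ii[p]), int(jj[p])
                expr = c_low * mz[i] + c_high * mz[j]
                matched, loss = _first_matching_loss(
                    expr, c_low, c_high, target, tolerance.tol, constants, losses_enabled
                )
                assert matched  # mask and scalar test share the same arithmetic
                relations.append(PairRelation(i, j, kind, z, loss))
    return relations


def doubly_charged_flags(
    spectrum: Spectrum,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
) -> np.ndarray:
    """Boolean flag per peak: is it consistent with a +2 fragment ion?

    A peak is flagged when (a) a +1 counterpart exists at ``2*mz - proton``
    within tolerance, or (b) it is the +2-designated member of some
    (+1, +2) complementary pair under the z = 3 hypothesis. Neutral losses
    are not applied here.
    """
    n = len(spectrum)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    mz = spectrum.mz
    tol = tolerance.tol
    # (a) +1 counterpart at 2*mz - proton
    counterpart = 2.0 * mz - constants.proton
    dist = np.abs(counterpart[:, None] - mz[None, :])
    np.fill_diagonal(dist, np.inf)
    flags |= np.any(dist <= tol, axis=1)
    if n >= 2:
        ii, jj, masks = pair_relation_masks(spectrum, constants, tolerance, losses_enabled=False)
        flags[ii[masks[("CP12_LOW2", 3)]]] = True
        flags[jj[masks[("CP12_HIGH2", 3)]]] = True
    return flags


def is_doubly_charged_peak(
    k: int,
    spectrum: Spectrum,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
) -> bool:
    """Scalar form of :func:`doubly_charged_flags` for peak index ``k``."""
    if not 0 <= k < len(spectrum):
        raise IndexError(f"peak index {k} out of range")
    return bool(doubly_charged_flags(spectrum, constants, tolerance)[k])


def basic_site_pair_mask(
    spectrum: Spectrum,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance: Tolerance = Tolerance(),
    losses_enabled: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairs whose m/z difference matches a basic-residue mass (K, R, H).

    Returns pair index arrays (i, j) and a boolean mask. Adding a neutral
    loss back to the higher member raises the difference by the loss mass;
    adding it to the lower member reduces it, so the loss variants reduce
    to symmetric shifts of the difference.
    """
    n = len(spectrum)
    ii, jj = _pair_indices(n)
    if n < 2:
        return ii, jj, np.zeros(0, dtype=bool)
    diffs = spectrum.mz[jj] - spectrum.mz[ii]
    losses = _loss_values(constants)
    if losses_enabled:
        shifts = np.concatenate([[0.0], losses, -losses])
    else:
        shifts = np.zeros(1)
    mask = np.zeros(ii.size, dtype=bool)
    for residue in sorted(constants.basic_residues):
        mask |= _match_any(diffs, constants.residue_masses[residue], tolerance.tol, shifts)
    return ii, jj, mask
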