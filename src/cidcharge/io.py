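"""Reading and writing spectrum collections and prediction tables.

MGF (Mascot generic format) is the canonical interchange format; parsing
and serialization are delegated to :mod:`pyteomics.mgf`, with this module
enforcing the package's peak-list canonicalization (sorting, duplicate
merging, zero-intensity removal) and the charge-label policy: a CHARGE
line is interpreted as a known label only when it reads ``2+`` or ``3+``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .spectra import Spectrum, SpectrumCollection

PREDICTION_COLUMNS = (
    "spectrum_id",
    "delta_cp",
    "delta_rcp",
    "i_dc",
    "n_bs",
    "posterior_plus3",
    "predicted_charge",
)


def _parse_charge(params: dict) -> int | None:
    raw = params.get("charge")
    if not raw:
        return None
    try:
        value = int(raw[0])
    except (TypeError, ValueError):
        return None
    return value if value in (2, 3) else None


def read_mgf(path: str | Path) -> SpectrumCollection:
    """Read an MGF file into a :class:`SpectrumCollection`.

    Each BEGIN IONS/END IONS block becomes one spectrum. The first PEPMASS
    token is taken verbatim as the precursor m/z; the CHARGE line is parsed
    into ``true_charge`` only when it is ``2+`` or ``3+``. Malformed blocks
    raise a :class:`ValueError` naming the 1-based block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    seen_ids: set[str] = set()
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        index = 0
        while True:
            index += 1
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # noqa: BLE001 - re-raise with block context
                raise ValueError(f"malformed MGF block {index} in {path}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"malformed MGF block {index} in {path}: missing PEPMASS")
            title = str(params.get("title", "")).strip() or f"spectrum-{index}"
            if title in seen_ids:
                title = f"{title}#{index}"
            seen_ids.add(title)
            try:
                spectrum = Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    true_charge=_parse_charge(params),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed MGF block {index} in {path}: {exc}") from exc
            spectra.append(spectrum)
    if not spectra:
        raise ValueError(f"no spectra found in {path}")
    return SpectrumCollection(spectra=spectra, source_path=str(path))


def write_mgf(collection: SpectrumCollection | Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF. CHARGE is emitted only for labeled spectra."""
    spectra = list(collection)
    if not spectra:
        raise ValueError("refusing to write an empty spectrum collection")
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.true_charge is not None:
            params["charge"] = s.true_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w", newline="\n") as handle:
        _mgf.write(entries, handle, key_order=["title", "pepmass", "charge"])


def write_predictions(rows: Sequence[dict], path: str | Path) -> None:
    """Write the per-spectrum prediction table as TSV.

    ``rows`` are mappings with the columns in :data:`PREDICTION_COLUMNS`
    (spectrum id, the four raw feature values, the posterior probability of
    charge +3 and the assigned charge). Floats are written with six decimal
    places so the table round-trips feature values to that precision.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty prediction table")
    frame = pd.DataFrame(rows)
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"prediction rows missing columns: {missing}")
    frame = frame[list(PREDICTION_COLUMNS)]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is not a prediction table; missing {missing}")
    frame["predicted_charge"] = frame["predicted_charge"].astype(int)
    return frame


def write_roc_points(points: np.ndarray, path: str | Path) -> None:
    """Export ROC points as a two-column TSV (fpr, tpr)."""
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
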