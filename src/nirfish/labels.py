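"""Sample-label codes and spectra-table input/output.

Each measurement in the study carries a fixed 9-character code, e.g.
``MF07T24_2``: sampling site (``E`` eye, ``G`` gill, ``M`` muscle, ``S``
skin), fish number (``F`` + two digits), group (``C`` control / ``T``
treated), exposure term in hours (``03`` or ``24``), and replicate
(``_`` + digit).  Spectra travel as wide CSV tables whose column headers
are wavelengths in nm.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SITES = {"E": "eye", "G": "gill", "M": "muscle", "S": "skin"}
GROUPS = {"C": "control", "T": "treated"}
TERMS = (3, 24)

_LABEL_RE = re.compile(r"^([A-Z])F(\d{2})([A-Z])(\d{2})_(\d)$")


class LabelError(ValueError):
    """A sample code does not follow the 9-character layout."""


@dataclass(frozen=True)
class SampleLabel:
    """Parsed 9-character sample code."""

    site: str
    fish_id: int
    group: str
    term_hours: int
    replicate: int

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise LabelError(f"unknown site {self.site!r} (expected one of {sorted(SITES)})")
        if self.group not in GROUPS:
            raise LabelError(f"unknown group {self.group!r} (expected 'C' or 'T')")
        if self.term_hours not in TERMS:
            raise LabelError(f"term must be 3 or 24 h, got {self.term_hours}")
        if not 1 <= self.fish_id <= 99:
            raise LabelError(f"fish_id must be in 1..99, got {self.fish_id}")
        if not 1 <= self.replicate <= 9:
            raise LabelError(f"replicate must be in 1..9, got {self.replicate}")

    @property
    def is_treated(self) -> bool:
        return self.group == "T"


def parse_label(code: str) -> SampleLabel:
    """Parse a 9-character sample code into its fields.

    Raises :class:`LabelError` naming the offending field for malformed
    input.
    """
    if len(code) != 9:
        raise LabelError(f"label {code!r} has length {len(code)}, expected 9")
    m = _LABEL_RE.match(code)
    if m is None:
        raise LabelError(f"label {code!r} does not match the site/F##/group/term/_rep layout")
    site, fish, group, term, rep = m.groups()
    if site not in SITES:
        raise LabelError(f"label {code!r}: unknown site {site!r}")
    if group not in GROUPS:
        raise LabelError(f"label {code!r}: unknown group {group!r}")
    if int(term) not in TERMS:
        raise LabelError(f"label {code!r}: term {term!r} not in {{03, 24}}")
    return SampleLabel(site, int(fish), group, int(term), int(rep))


def format_label(label: SampleLabel) -> str:
    """Inverse of :func:`parse_label`."""
    return f"{label.site}F{label.fish_id:02d}{label.group}{label.term_hours:02d}_{label.replicate}"


@dataclass
class SpectrumSet:
    """A block of spectra with aligned metadata.

    Rows are individual acquisitions; ``wavelengths`` (nm, strictly
    increasing) index the columns of ``intensities``.  ``day`` is the
    analysis-day index used to group paired fish in cross-validation.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    labels: list[SampleLabel]
    day: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.day = np.asarray(self.day, dtype=int)
        n, p = self.intensities.shape
        if len(self.labels) != n or len(self.day) != n:
            raise ValueError(
                f"row mismatch: {n} intensity rows, {len(self.labels)} labels, {len(self.day)} days"
            )
        if self.wavelengths.shape != (p,):
            raise ValueError(f"{p} intensity columns but {self.wavelengths.size} wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[1]

    def classes(self) -> np.ndarray:
        """Class coding: control -> 0, treated -> 1."""
        return np.array([1 if l.is_treated else 0 for l in self.labels], dtype=int)

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "SpectrumSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectrumSet(
            self.wavelengths.copy(),
            self.intensities[index].copy(),
            [self.labels[i] for i in index],
            self.day[index].copy(),
        )

    def subset_wavelengths(self, index: Sequence[int] | np.ndarray) -> "SpectrumSet":
        index = np.asarray(index)
        return SpectrumSet(
            self.wavelengths[index].copy(),
            self.intensities[:, index].copy(),
            list(self.labels),
            self.day.copy(),
        )

    def select(self, site: str | None = None, term_hours: int | None = None) -> "SpectrumSet":
        """Rows for one sample matrix and/or one exposure term."""
        keep = [
            i
            for i, l in enumerate(self.labels)
            if (site is None or l.site == site) and (term_hours is None or l.term_hours == term_hours)
        ]
        return self.subset_rows(keep)

    def replace_intensities(self, values: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectrumSet":
        wl = self.wavelengths if wavelengths is None else np.asarray(wavelengths, dtype=float)
        return SpectrumSet(wl.copy(), np.asarray(values, dtype=float), list(self.labels), self.day.copy())


def _read_header(path) -> list[str]:
    with open(path, newline="") as fh:
        return next(csv.reader(fh))


def read_spectra_table(
    path,
    label_column: str = "label",
    day_column: str | None = "day",
    fish_day_map: Mapping[int, int] | None = None,
) -> SpectrumSet:
    """Read a wide spectra CSV into a :class:`SpectrumSet`.

    Wavelength columns are recognised by numeric headers (nm) and sorted
    ascending.  Days come from ``day_column`` when present, otherwise from
    an explicit ``fish_day_map`` (fish id -> analysis day): the label code
    itself does not encode the day, yet the paired cross-validation needs
    it, so the mapping must be supplied one way or the other.
    """
    header = _read_header(path)
    wl_headers = [h for h in header if _is_number(h)]
    if len(set(wl_headers)) != len(wl_headers):
        dupes = sorted({h for h in wl_headers if wl_headers.count(h) > 1})
        raise ValueError(f"duplicate wavelength column header(s): {dupes}")
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    labels = [parse_label(str(code)) for code in df[label_column]]

    wl_cols = [h for h in header if _is_number(h)]
    block = df[wl_cols]
    bad = block.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"non-numeric intensity cell at row {r}, wavelength column {wl_cols[c]!r}")
    for col in wl_cols:
        if not np.issubdtype(block[col].dtype, np.number):
            r = int(np.flatnonzero(pd.to_numeric(block[col], errors="coerce").isna())[0])
            raise ValueError(f"non-numeric intensity cell at row {r}, wavelength column {col!r}")

    wavelengths = np.array([float(h) for h in wl_cols])
    order = np.argsort(wavelengths)
    intensities = block.to_numpy(dtype=float)[:, order]
    wavelengths = wavelengths[order]

    if day_column is not None and day_column in df.columns:
        day = df[day_column].to_numpy(dtype=int)
    elif fish_day_map is not None:
        try:
            day = np.array([fish_day_map[l.fish_id] for l in labels], dtype=int)
        except KeyError as e:
            raise ValueError(f"fish {e.args[0]} missing from fish_day_map") from None
    else:
        raise ValueError("no day column found and no fish_day_map supplied")
    return SpectrumSet(wavelengths, intensities, labels, day)


def write_spectra_table(spectra: SpectrumSet, path, label_column: str = "label", day_column: str = "day") -> None:
    """Inverse of :func:`read_spectra_table` (same CSV dialect)."""
    df = pd.DataFrame(spectra.intensities, columns=[_format_wl(w) for w in spectra.wavelengths])
    df.insert(0, day_column, spectra.day)
    df.insert(0, label_column, [format_label(l) for l in spectra.labels])
    df.to_csv(path, index=False)


def _format_wl(w: float) -> str:
    return f"{w:.6f}".rstrip("0").rstrip(".")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


@dataclass
class ReportRecord:
    """One row of the classification report: a (matrix, term, pretreatment) model."""

    matrix: str
    term_hours: int
    pretreatment: str
    n_variables: int
    n_lv: int
    acc_cal: float
    acc_cv: float
    ner_cal: float
    ner_cv: float


REPORT_COLUMNS = [
    "SampleMatrix",
    "Effect",
    "Pre-Treatment",
    "N° Variables",
    "N° LV",
    "Acc% cal",
    "Acc% cv",
    "NER% cal",
    "NER% cv",
]

_TERM_NAMES = {3: "Short-term", 24: "Long-term"}
_PRETREAT_NAMES = {"snv": "SNV", "der1": "Der1", "der2": "Der2"}


def write_report(results: Iterable[ReportRecord], path) -> None:
    """Write the classification report CSV (one row per model, accuracies to 2 dp)."""
    rows = []
    for r in results:
        rows.append(
            {
                "SampleMatrix": SITES.get(r.matrix, r.matrix).capitalize(),
                "Effect": _TERM_NAMES.get(r.term_hours, str(r.term_hours)),
                "Pre-Treatment": _PRETREAT_NAMES.get(r.pretreatment, r.pretreatment),
                "N° Variables": r.n_variables,
                "N° LV": r.n_lv,
                "Acc% cal": f"{r.acc_cal:.2f}",
                "Acc% cv": f"{r.acc_cv:.2f}",
                "NER% cal": f"{r.ner_cal:.2f}",
                "NER% cv": f"{r.ner_cv:.2f}",
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)
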