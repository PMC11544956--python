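"""Paired-day leave-more-out cross-validation.

The study design measures one control and one treated fish per analysis
day, with three replicate spectra per fish and matrix.  The cancellation
group of a day is *all* replicate rows of both fish measured that day;
groups are held out whole, so no replicate of a held-out fish, nor its
paired partner, ever informs the model that predicts it.  For the study
design (6 days per exposure term) this yields 6 groups of 6 rows.

Everything that must be learned from data — column autoscaling and the
PLS-DA fit — is recomputed inside each fold on the training groups only.
Row-local pretreatments (SNV, derivatives) and per-day pair-centering use
no cross-row/cross-day statistics and are applied before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import SpectrumSet, format_label
from .plsda import (
    ClassificationMetrics,
    classification_metrics,
    fit_plsda,
    predict,
    vip_scores,
)


@dataclass
class CVGroup:
    day: int
    fish_ids: tuple[int, ...]
    rows: np.ndarray


@dataclass
class CVScheme:
    """Partition of row indices into cancellation groups (one per day)."""

    groups: list[CVGroup]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def covered_rows(self) -> np.ndarray:
        return np.concatenate([g.rows for g in self.groups])


def build_day_groups(spectra: SpectrumSet, term_hours: int | None = None) -> CVScheme:
    """Group rows by analysis day; validate the paired structure.

    ``term_hours`` filters nothing — it asserts the rows already belong to
    one exposure term (pass ``None`` to skip the check).
    """
    if term_hours is not None:
        terms = {l.term_hours for l in spectra.labels}
        if terms != {term_hours}:
            raise ValueError(f"rows span terms {sorted(terms)}, expected only {term_hours}")
    # a fish's replicates must sit on a single day
    fish_days: dict[int, set[int]] = {}
    for l, d in zip(spectra.labels, spectra.day):
        fish_days.setdefault(l.fish_id, set()).add(int(d))
    split = {f: sorted(ds) for f, ds in fish_days.items() if len(ds) > 1}
    if split:
        raise ValueError(f"replicates of fish {sorted(split)} span multiple days: {split}")
    groups = []
    for d in np.unique(spectra.day):
        rows = np.flatnonzero(spectra.day == d)
        classes = {spectra.labels[i].group for i in rows}
        if classes != {"C", "T"}:
            raise ValueError(f"day {int(d)} lacks both classes (has {sorted(classes)})")
        fish = tuple(sorted({spectra.labels[i].fish_id for i in rows}))
        groups.append(CVGroup(day=int(d), fish_ids=fish, rows=rows))
    return CVScheme(groups=groups)


@dataclass
class CVResult:
    """Pooled leave-more-out results for one component count."""

    n_components: int
    accuracy_cv: float
    ner_cv: float
    mean_vip: np.ndarray
    y_hat: np.ndarray            # pooled continuous responses, row order of the input
    y_pred: np.ndarray
    fold_of_row: np.ndarray
    metrics: ClassificationMetrics
    fold_models: list = None     # one fitted PLSDAModel per cancellation group


def cv_evaluate_multi(
    spectra: SpectrumSet,
    scheme: CVScheme,
    a_max: int,
) -> list[CVResult]:
    """Leave-more-out CV for every component count 1..a_max in one sweep.

    PLS components are nested, so each fold is fitted once with ``a_max``
    components and truncated for smaller counts.  Returns one
    :class:`CVResult` per component count (index 0 -> 1 component).
    """
    y = spectra.classes()
    n = spectra.n_rows
    covered = np.sort(scheme.covered_rows())
    if covered.size != n or np.any(covered != np.arange(n)):
        raise ValueError("scheme must cover every row exactly once")

    a_eff = a_max
    for g in scheme.groups:
        n_train = n - g.rows.size if scheme.n_groups > 1 else n
        a_eff = min(a_eff, n_train - 1, spectra.n_wavelengths)
    if a_eff < 1:
        raise ValueError("training folds too small for even one component")

    y_hat = np.full((a_eff, n), np.nan)
    vips = np.zeros((a_eff, spectra.n_wavelengths))
    fold_of_row = np.full(n, -1, dtype=int)
    fold_models = []
    for k, g in enumerate(scheme.groups):
        train = np.setdiff1d(np.arange(n), g.rows)
        if train.size == 0:
            # degenerate single-group scheme: self-evaluation == calibration
            train = g.rows
        if np.unique(y[train]).size < 2:
            raise ValueError(f"training rows for held-out day {g.day} contain a single class")
        model = fit_plsda(spectra.intensities[train], y[train], a_eff, autoscale=True)
        fold_models.append(model)
        for a in range(1, a_eff + 1):
            resp, _ = predict(model, spectra.intensities[g.rows], n_components=a)
            y_hat[a - 1, g.rows] = resp
            vips[a - 1] += vip_scores(model, n_components=a)
        fold_of_row[g.rows] = k
    vips /= scheme.n_groups

    results = []
    for a in range(1, a_eff + 1):
        pred = (y_hat[a - 1] >= 0.5).astype(int)
        m = classification_metrics(y, pred)
        results.append(
            CVResult(
                n_components=a,
                accuracy_cv=m.accuracy,
                ner_cv=m.ner,
                mean_vip=vips[a - 1],
                y_hat=y_hat[a - 1].copy(),
                y_pred=pred,
                fold_of_row=fold_of_row.copy(),
                metrics=m,
                fold_models=fold_models,
            )
        )
    return results


def cv_evaluate(spectra: SpectrumSet, scheme: CVScheme, n_components: int) -> CVResult:
    """Leave-more-out CV at a single component count."""
    results = cv_evaluate_multi(spectra, scheme, n_components)
    if len(results) < n_components:
        raise ValueError(
            f"folds support at most {len(results)} components, requested {n_components}"
        )
    return results[n_components - 1]


def export_fold_predictions(spectra: SpectrumSet, result: CVResult):
    """Per-row CV prediction table (label, day, fold, truth, response, class)."""
    import pandas as pd

    y = spectra.classes()
    return pd.DataFrame(
        {
            "label": [format_label(l) for l in spectra.labels],
            "day": spectra.day,
            "fold": result.fold_of_row,
            "true_class": y,
            "y_hat": result.y_hat,
            "predicted_class": result.y_pred,
        }
    )
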