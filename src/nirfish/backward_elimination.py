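"""VIP-driven backward elimination around cross-validated PLS-DA.

Each cycle evaluates every component count 1..A_max by paired-day CV on
the current wavelength subset, keeps the best count, ranks wavelengths by
the fold-averaged VIP at that count, and drops the lowest-VIP ones — at
most 6% of the current set (never fewer than one).  The loop runs down to
a floor p_min and the cycle with the best CV accuracy wins, ties going to
fewer wavelengths, then fewer latent variables, then the earlier cycle.
The whole procedure is deterministic: the only tie-break among equal VIPs
is ascending wavelength index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .crossval import CVScheme, cv_evaluate_multi
from .labels import SpectrumSet
from .plsda import PLSDAModel, classification_metrics, fit_plsda

logger = logging.getLogger(__name__)

ELIMINATION_FRACTION = 0.06  # at most this share of current wavelengths removed per cycle


@dataclass
class BECycle:
    cycle: int
    retained: np.ndarray               # wavelength indices into the original grid
    accuracy_cv_per_a: np.ndarray      # index a-1 -> CV accuracy with a components
    ner_cv_per_a: np.ndarray
    best_a: int
    mean_vip: np.ndarray               # fold-mean VIP at best_a, aligned with `retained`
    removed: np.ndarray                # indices removed after this cycle


@dataclass
class BEResult:
    """Elimination trace plus the selected model."""

    trace: list[BECycle]
    selected_cycle: int
    selected_wavelength_index: np.ndarray
    selected_wavelengths: np.ndarray
    n_components: int
    accuracy_cal: float
    ner_cal: float
    accuracy_cv: float
    ner_cv: float
    model: PLSDAModel = field(repr=False)

    def longest_surviving(self, k: int) -> np.ndarray:
        """The k wavelengths (original indices) eliminated last, or never.

        The elimination order is how BE ranks wavelengths overall; the
        longest survivors are its estimate of the informative set of size
        k, independent of which trace cycle won the accuracy contest.
        """
        order: list[int] = []
        for c in self.trace:
            order.extend(c.removed.tolist())
        survivors = [i for i in self.trace[0].retained.tolist() if i not in order]
        ranked = order + survivors  # first eliminated ... never eliminated
        return np.array(sorted(ranked[-k:]))


def n_to_remove(p: int, fraction: float = ELIMINATION_FRACTION) -> int:
    """Wavelengths dropped from a p-wavelength cycle: max(1, floor(fraction*p))."""
    return max(1, math.floor(fraction * p))


def be_plsda(
    spectra: SpectrumSet,
    scheme: CVScheme,
    a_max: int = 5,
    elimination_fraction: float = ELIMINATION_FRACTION,
    p_min: int | None = None,
) -> BEResult:
    """Backward elimination over ``spectra``'s wavelengths.

    ``spectra`` must already be pretreated (SNV/derivative, pair-centering);
    autoscaling and PLS fits happen inside the CV folds.
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    if not 0 < elimination_fraction < 1:
        raise ValueError("elimination_fraction must be in (0, 1)")
    if p_min is None:
        p_min = a_max + 1
    if p_min < 2:
        raise ValueError("p_min must be >= 2")
    p0 = spectra.n_wavelengths
    if p_min >= p0:
        raise ValueError(f"p_min={p_min} must be below the initial wavelength count {p0}")

    retained = np.arange(p0)
    trace: list[BECycle] = []
    cycle = 0
    while retained.size >= p_min:
        sub = spectra.subset_wavelengths(retained)
        per_a = cv_evaluate_multi(sub, scheme, min(a_max, retained.size))
        acc = np.array([r.accuracy_cv for r in per_a])
        ner = np.array([r.ner_cv for r in per_a])
        best_a = int(np.argmax(acc)) + 1  # argmax takes the smallest index on ties
        vip = per_a[best_a - 1].mean_vip

        k = n_to_remove(retained.size, elimination_fraction)
        # stable sort: ascending VIP, ties broken by ascending wavelength index
        order = np.argsort(vip, kind="stable")
        removed = retained[np.sort(order[:k])]
        trace.append(
            BECycle(
                cycle=cycle,
                retained=retained.copy(),
                accuracy_cv_per_a=acc,
                ner_cv_per_a=ner,
                best_a=best_a,
                mean_vip=vip,
                removed=removed,
            )
        )
        logger.info(
            "BE cycle %d: p=%d best_A=%d Acc%%cv=%.2f (removing %d)",
            cycle, retained.size, best_a, acc[best_a - 1], k,
        )
        retained = np.setdiff1d(retained, removed)
        cycle += 1

    # winner: max CV accuracy; ties -> fewer wavelengths -> fewer LVs -> earlier cycle.
    # Trace sizes strictly decrease, so "fewer wavelengths" prefers the later cycle.
    best = max(
        range(len(trace)),
        key=lambda i: (
            trace[i].accuracy_cv_per_a[trace[i].best_a - 1],
            -trace[i].retained.size,
            -trace[i].best_a,
            -trace[i].cycle,
        ),
    )
    sel = trace[best]
    sel_idx = sel.retained
    sub = spectra.subset_wavelengths(sel_idx)
    model = fit_plsda(sub.intensities, sub.classes(), sel.best_a, autoscale=True)
    cal = classification_metrics(sub.classes(), (model.fitted_response >= model.threshold).astype(int))
    return BEResult(
        trace=trace,
        selected_cycle=sel.cycle,
        selected_wavelength_index=sel_idx.copy(),
        selected_wavelengths=spectra.wavelengths[sel_idx].copy(),
        n_components=sel.best_a,
        accuracy_cal=cal.accuracy,
        ner_cal=cal.ner,
        accuracy_cv=float(sel.accuracy_cv_per_a[sel.best_a - 1]),
        ner_cv=float(sel.ner_cv_per_a[sel.best_a - 1]),
        model=model,
    )


def export_trace(result: BEResult, wavelengths: np.ndarray):
    """BE trace as a table (cycle, p, best A, Acc%cv, NER%cv, removed wavelengths)."""
    import pandas as pd

    rows = []
    for c in result.trace:
        rows.append(
            {
                "cycle": c.cycle,
                "p": c.retained.size,
                "best_A": c.best_a,
                "acc_cv": round(c.accuracy_cv_per_a[c.best_a - 1], 2),
                "ner_cv": round(c.ner_cv_per_a[c.best_a - 1], 2),
                "removed_wavelengths": ";".join(f"{wavelengths[i]:.1f}" for i in c.removed),
            }
        )
    return pd.DataFrame(rows)
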