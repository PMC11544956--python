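"""Full-analysis orchestration.

For every (sample matrix, exposure term, pretreatment) combination the
pipeline filters the rows, applies the pretreatment (plus optional
paired-day centering), builds the day-level cancellation groups, runs
backward-elimination PLS-DA, and emits one report row with the selected
wavelength count, component count, and calibration / cross-validation
accuracy and non-error rate.  Per (matrix, term) the best pretreatment's
model also yields latent-variable score and coefficient exports, and the
short- vs long-term models are compared by coefficient sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backward_elimination import BEResult, be_plsda, export_trace
from .crossval import build_day_groups
from .labels import ReportRecord, SpectrumSet, format_label, read_spectra_table, write_report
from .preprocess import PRETREATMENTS, apply_pretreatment
from .plsda import transform
from .simulate import preset, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """What to analyse and how."""

    input_path: str | None = None          # spectra CSV; mutually exclusive with preset
    preset: str | None = None              # synthetic preset name
    matrices: tuple[str, ...] = ("E", "G", "M", "S")
    terms: tuple[int, ...] = (3, 24)
    pretreatments: tuple[str, ...] = ("snv", "der1", "der2")
    a_max: int = 5
    elimination_fraction: float = 0.06
    day_center: bool = True
    snv_first: bool = False
    out_dir: str | None = None
    seed: int = 0                          # synthetic input only
    label_column: str = "label"
    day_column: str = "day"

    def __post_init__(self) -> None:
        if not self.matrices or not self.terms or not self.pretreatments:
            raise ValueError("need at least one matrix, term and pretreatment")
        bad = [p for p in self.pretreatments if p not in PRETREATMENTS]
        if bad:
            raise ValueError(f"unknown pretreatment(s) {bad}")
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path or preset must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("matrices", "terms", "pretreatments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisResult:
    """Everything run_analysis computes, before any file is written."""

    records: list[ReportRecord]
    be_results: dict[tuple[str, int, str], BEResult]
    best: dict[tuple[str, int], str]       # (matrix, term) -> winning pretreatment
    spectra: SpectrumSet


def load_input(config: RunConfig) -> SpectrumSet:
    if config.preset is not None:
        spectra, _ = simulate_study(preset(config.preset, seed=config.seed))
        return spectra
    return read_spectra_table(config.input_path, config.label_column, config.day_column)


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run BE-PLS-DA per (matrix, term, pretreatment); optionally write artifacts."""
    spectra = load_input(config)
    records: list[ReportRecord] = []
    be_results: dict[tuple[str, int, str], BEResult] = {}
    best: dict[tuple[str, int], str] = {}

    for matrix in config.matrices:
        for term in config.terms:
            subset = spectra.select(site=matrix, term_hours=term)
            if subset.n_rows == 0:
                raise ValueError(f"no rows for matrix {matrix!r}, term {term} h")
            for pre in config.pretreatments:
                logger.info("analysing matrix=%s term=%dh pretreatment=%s", matrix, term, pre)
                treated = apply_pretreatment(subset, pre, day_center=config.day_center,
                                             snv_first=config.snv_first)
                scheme = build_day_groups(treated, term_hours=term)
                res = be_plsda(
                    treated,
                    scheme,
                    a_max=config.a_max,
                    elimination_fraction=config.elimination_fraction,
                )
                be_results[(matrix, term, pre)] = res
                records.append(
                    ReportRecord(
                        matrix=matrix,
                        term_hours=term,
                        pretreatment=pre,
                        n_variables=int(res.selected_wavelength_index.size),
                        n_lv=res.n_components,
                        acc_cal=res.accuracy_cal,
                        acc_cv=res.accuracy_cv,
                        ner_cal=res.ner_cal,
                        ner_cv=res.ner_cv,
                    )
                )
            best[(matrix, term)] = max(
                config.pretreatments,
                key=lambda p: (
                    be_results[(matrix, term, p)].accuracy_cv,
                    -be_results[(matrix, term, p)].selected_wavelength_index.size,
                    -be_results[(matrix, term, p)].n_components,
                ),
            )

    result = AnalysisResult(records=records, be_results=be_results, best=best, spectra=spectra)
    if config.out_dir is not None:
        write_artifacts(result, config)
    return result


def write_artifacts(result: AnalysisResult, config: RunConfig) -> None:
    """Report CSV plus, per (matrix, term), the best model's exports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report(result.records, out / "report.csv")
    for (matrix, term), pre in result.best.items():
        res = result.be_results[(matrix, term, pre)]
        stem = f"{matrix}_{term:02d}h_{pre}"
        subset = result.spectra.select(site=matrix, term_hours=term)
        treated = apply_pretreatment(subset, pre, day_center=config.day_center,
                                     snv_first=config.snv_first)
        scores_df = score_export(treated, res)
        scores_df.to_csv(out / f"scores_{stem}.csv", index=False)
        coef_df = coefficient_export(res)
        coef_df.to_csv(out / f"coefficients_{stem}.csv", index=False)
        export_trace(res, treated.wavelengths).to_csv(out / f"be_trace_{stem}.csv", index=False)


def score_export(treated: SpectrumSet, res: BEResult) -> pd.DataFrame:
    """Latent-variable scores of every row under the selected model."""
    sub = treated.subset_wavelengths(res.selected_wavelength_index)
    T = transform(res.model, sub.intensities)
    df = pd.DataFrame(T, columns=[f"LV{a}" for a in range(1, res.n_components + 1)])
    df.insert(0, "day", sub.day)
    df.insert(0, "label", [format_label(l) for l in sub.labels])
    return df


def coefficient_export(res: BEResult) -> pd.DataFrame:
    """Selected wavelengths and their collapsed regression coefficients."""
    return pd.DataFrame(
        {"wavelength_nm": res.selected_wavelengths, "coefficient": res.model.coef}
    )


@dataclass
class TermComparison:
    """Coefficient-sign comparison of the best short- and long-term models."""

    shared_wavelengths: np.ndarray
    opposite_sign_fraction: float
    table: pd.DataFrame


def compare_terms(short: BEResult, long_: BEResult) -> TermComparison:
    """Fraction of shared selected wavelengths whose coefficients flip sign.

    A large fraction means the treatment moves the same bands in opposite
    directions at the two exposure terms (fresh-vs-treated versus
    stored-vs-treated contrasts).
    """
    common, i_s, i_l = np.intersect1d(
        short.selected_wavelengths, long_.selected_wavelengths, return_indices=True
    )
    if common.size == 0:
        logger.warning("no shared wavelengths between short- and long-term models")
        empty = pd.DataFrame(columns=["wavelength_nm", "coef_short", "coef_long", "opposite_sign"])
        return TermComparison(common, float("nan"), empty)
    cs, cl = short.model.coef[i_s], long_.model.coef[i_l]
    opposite = np.sign(cs) * np.sign(cl) < 0
    table = pd.DataFrame(
        {
            "wavelength_nm": common,
            "coef_short": cs,
            "coef_long": cl,
            "opposite_sign": opposite,
        }
    )
    return TermComparison(common, float(opposite.mean()), table)
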