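"""Cohort model: from raw scans to fitted paired-eye flow statistics.

The modelling surface follows the statsmodels convention: build a
:class:`CohortFlowModel` from data (either a per-eye measures table or raw
cohort scans via :meth:`CohortFlowModel.from_cohort`), call :meth:`fit`,
and read estimates, p-values and diagnostics off the returned
:class:`CohortFlowResults`, whose :meth:`summary` prints the full set of
tables.  Plotting hangs off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peripapillary import compute_mv_mt, make_annulus
from .perfusion import mean_arterial_pressure, ocular_perfusion_pressure
from .scan_io import CohortPatient, LSFGScan
from .stats import (
    SpearmanMatrix,
    average_scans,
    linreg_vs_time,
    paired_differences,
    paired_t,
    spearman_matrix,
)
from .superpixel import DEFAULT_BIN_EDGES, bin_histogram, slic_segment, superpixel_means

__all__ = ["CohortFlowModel", "CohortFlowResults", "analyze_scan", "MEASURES"]

logger = logging.getLogger("lsfg_superpix")

#: Per-eye outcome measures carried through the cohort statistics.
MEASURES = ["mv", "mt", "pct_ge20", "pct_lt5", "pct_5_10", "pct_10_15", "pct_15_20"]

#: Measures regressed on time from treatment (the headline flow readouts).
REGRESSION_MEASURES = ["mv", "mt", "pct_ge20", "pct_lt5"]

#: Fig-style variable labels for the correlation matrix.
_SPEARMAN_VARS = [
    "mv", "mt", "pct_ge20", "pct_lt5",
    "time_from_treatment", "dose_to_disc", "distance_to_disc",
]


def analyze_scan(
    scan: LSFGScan,
    disc_center: tuple[float, float],
    disc_radius: float,
    n_superpixels: int = 1500,
    compactness: float = 50.0,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    exclude_mask: np.ndarray | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """All per-scan measures: annulus MV/MT plus the five superpixel ranges.

    ``exclude_mask`` (optional, True = exclude) removes regions — e.g. a
    tumor shadow — from the whole-frame superpixel histogram by treating
    them as invalid.
    """
    annulus = make_annulus(disc_center, disc_radius, scan.shape)
    peri = compute_mv_mt(scan, annulus)
    sp_scan = scan
    if exclude_mask is not None:
        if exclude_mask.shape != scan.shape:
            raise ValueError("exclusion mask shape does not match the scan")
        sp_scan = LSFGScan(
            mbr=scan.mbr, valid=scan.valid & ~exclude_mask,
            patient_id=scan.patient_id, eye=scan.eye,
            irradiated=scan.irradiated, scan_index=scan.scan_index,
        )
    seg = slic_segment(sp_scan, n_target=n_superpixels, compactness=compactness,
                       seed=seed)
    seg.bin_edges = tuple(bin_edges)
    superpixel_means(sp_scan, seg)
    hist = bin_histogram(seg)
    return {
        "mv": peri.mv,
        "mt": peri.mt,
        "threshold": peri.threshold,
        "pct_lt5": hist.percent[0],
        "pct_5_10": hist.percent[1],
        "pct_10_15": hist.percent[2],
        "pct_15_20": hist.percent[3],
        "pct_ge20": hist.percent[4],
        "n_defined_superpixels": hist.n_defined,
    }


class CohortFlowModel:
    """Paired-eye flow statistics model over a per-eye measures table.

    Parameters
    ----------
    measures : DataFrame
        One row per (patient, eye) with at least ``patient_id``, ``eye``,
        ``irradiated`` and the outcome measures in :data:`MEASURES`, plus
        ``opp`` and the covariates ``time_from_treatment``,
        ``dose_to_disc``, ``distance_to_disc``.  Measure values are
        expected to be three-scan averages.
    """

    def __init__(self, measures: pd.DataFrame):
        required = {"patient_id", "eye", "irradiated", "time_from_treatment"}
        missing = required - set(measures.columns)
        if missing:
            raise ValueError(f"measures table missing columns: {sorted(missing)}")
        counts = measures.groupby("patient_id")["irradiated"].agg(["size", "sum"])
        bad = counts[(counts["size"] != 2) | (counts["sum"] != 1)]
        if len(bad):
            raise ValueError(
                f"each patient needs one irradiated and one fellow eye; bad: "
                f"{list(bad.index)}"
            )
        self.measures = measures.reset_index(drop=True)
        self.n_patients = measures["patient_id"].nunique()

    @classmethod
    def from_cohort(
        cls,
        patients: list[CohortPatient],
        n_superpixels: int = 1500,
        compactness: float = 50.0,
        bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
        exclude_mask: np.ndarray | None = None,
        seed: int | None = None,
        allow_missing_scans: bool = False,
    ) -> "CohortFlowModel":
        """Run the full per-scan analysis and average the three repeats."""
        rows = []
        for patient in patients:
            for eye, scans in sorted(patient.scans.items()):
                if len(scans) != 3 and not allow_missing_scans:
                    raise ValueError(
                        f"patient {patient.patient_id} eye {eye}: expected 3 scans, "
                        f"got {len(scans)}"
                    )
                per_scan = [
                    analyze_scan(
                        scan, patient.disc_center, patient.disc_radius,
                        n_superpixels=n_superpixels, compactness=compactness,
                        bin_edges=bin_edges, exclude_mask=exclude_mask, seed=seed,
                    )
                    for scan in scans
                ]
                row: dict[str, object] = {
                    "patient_id": patient.patient_id,
                    "eye": eye,
                    "irradiated": eye == patient.irradiated_eye,
                    "time_from_treatment": patient.time_from_treatment,
                    "dose_to_disc": patient.dose_to_disc,
                    "distance_to_disc": patient.distance_to_disc,
                }
                for name in MEASURES:
                    row[name] = average_scans(
                        [m[name] for m in per_scan], allow_missing=allow_missing_scans
                    )
                map_mmHg = mean_arterial_pressure(patient.sbp, patient.dbp)
                row["opp"] = ocular_perfusion_pressure(map_mmHg, patient.iop[eye])
                rows.append(row)
            logger.info("analyzed patient %s (%d scans)", patient.patient_id,
                        sum(len(s) for s in patient.scans.values()))
        return cls(pd.DataFrame(rows))

    def _aligned(self, measure: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Irradiated and fellow vectors aligned by patient."""
        wide = self.measures.pivot_table(
            index="patient_id", columns="irradiated", values=measure, sort=True
        )
        pids = list(wide.index)
        return wide[True].to_numpy(), wide[False].to_numpy(), pids

    def fit(self, alpha: float = 0.01, bonferroni: bool = False) -> "CohortFlowResults":
        """Compute paired tests, time regressions, and the Spearman matrix."""
        paired_rows, diff_rows, reg_rows = [], [], []
        for measure in MEASURES + ["opp"]:
            irr, fellow, pids = self._aligned(measure)
            res = paired_t(irr, fellow)
            deltas, n_dec = paired_differences(irr, fellow)
            paired_rows.append({
                "measure": measure, "t": res.statistic, "p_value": res.p_value,
                "n": res.n, "mean_irradiated": float(np.mean(irr)),
                "mean_fellow": float(np.mean(fellow)),
                "n_decreased": n_dec,
            })
            for pid, delta in zip(pids, deltas):
                diff_rows.append({"patient_id": pid, "measure": measure,
                                  "delta": float(delta)})
        for measure in REGRESSION_MEASURES:
            for group, flag in (("irradiated", True), ("fellow", False)):
                sub = self.measures[self.measures["irradiated"] == flag]
                res = linreg_vs_time(sub["time_from_treatment"], sub[measure])
                reg_rows.append({
                    "measure": measure, "group": group, "slope": res.statistic,
                    "intercept": res.intercept, "p_value": res.p_value, "n": res.n,
                })
        irr_table = (
            self.measures[self.measures["irradiated"]]
            .set_index("patient_id")[_SPEARMAN_VARS]
        )
        spearman = spearman_matrix(irr_table, alpha=alpha, bonferroni=bonferroni,
                                   degenerate="nan")
        return CohortFlowResults(
            model=self,
            paired_tests=pd.DataFrame(paired_rows),
            differences=pd.DataFrame(diff_rows),
            regressions=pd.DataFrame(reg_rows),
            spearman=spearman,
            alpha=alpha,
        )


@dataclass
class CohortFlowResults:
    """Fitted cohort statistics with summary and plotting helpers."""

    model: CohortFlowModel
    paired_tests: pd.DataFrame
    differences: pd.DataFrame
    regressions: pd.DataFrame
    spearman: SpearmanMatrix
    alpha: float = 0.01

    @property
    def eye_measures(self) -> pd.DataFrame:
        return self.model.measures

    def summary(self) -> str:
        """Human-readable report of every fitted table."""
        lines = [
            "Paired-eye LSFG flow analysis",
            "=" * 64,
            f"Patients: {self.model.n_patients}   "
            f"(eyes: {len(self.model.measures)}; measures are 3-scan means)",
            "",
            "Paired two-tailed t-tests (irradiated vs fellow eye)",
            "-" * 64,
            self.paired_tests.to_string(index=False, float_format="%.4g"),
            "",
            "Linear regression vs time from treatment (slope per month)",
            "-" * 64,
            self.regressions.to_string(index=False, float_format="%.4g"),
            "",
            f"Spearman correlations (two-tailed, alpha = {self.alpha})",
            "-" * 64,
            self.spearman.to_long().to_string(index=False, float_format="%.4g"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # plotting (matplotlib, conveniences only)

    def plot_paired(self, measure: str, ax=None):
        """Irradiated-vs-fellow point pairs connected per patient."""
        import matplotlib.pyplot as plt

        irr, fellow, _ = self.model._aligned(measure)
        if ax is None:
            _, ax = plt.subplots()
        for a, b in zip(irr, fellow):
            ax.plot([0, 1], [b, a], "-", color="0.7", lw=0.8)
        ax.plot(np.zeros_like(fellow), fellow, "ko", label="fellow")
        ax.plot(np.ones_like(irr), irr, "o", color="purple", label="irradiated")
        ax.set_xticks([0, 1], ["fellow", "irradiated"])
        ax.set_ylabel(measure)
        ax.legend()
        return ax

    def plot_differences(self, measure: str, ax=None):
        """Per-patient irradiated-minus-fellow difference bars."""
        import matplotlib.pyplot as plt

        sub = self.differences[self.differences["measure"] == measure]
        if ax is None:
            _, ax = plt.subplots()
        order = sub.sort_values("delta")
        ax.bar(range(len(order)), order["delta"], color="steelblue")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xlabel("patient (sorted)")
        ax.set_ylabel(f"Δ {measure} (irradiated - fellow)")
        return ax

    def plot_time_trend(self, measure: str, ax=None):
        """Measure vs time from treatment with per-group OLS trendlines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"irradiated": "purple", "fellow": "black"}
        for group, flag in (("irradiated", True), ("fellow", False)):
            sub = self.model.measures[self.model.measures["irradiated"] == flag]
            ax.plot(sub["time_from_treatment"], sub[measure], "o",
                    color=colors[group], label=group, alpha=0.7)
            reg = self.regressions.query(
                "measure == @measure and group == @group"
            )
            if len(reg):
                xx = np.linspace(sub["time_from_treatment"].min(),
                                 sub["time_from_treatment"].max(), 50)
                row = reg.iloc[0]
                ax.plot(xx, row["intercept"] + row["slope"] * xx, "-",
                        color=colors[group], lw=1.2)
        ax.set_xlabel("time from treatment (months)")
        ax.set_ylabel(measure)
        ax.legend()
        return ax

    def plot_spearman_heatmap(self, ax=None):
        """Correlation heatmap with significant cells annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        rho = self.spearman.rho
        im = ax.imshow(rho.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(rho)), rho.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(rho)), rho.index)
        sig = self.spearman.significant()
        for i in range(len(rho)):
            for j in range(len(rho)):
                mark = "*" if sig.values[i, j] else ""
                ax.text(j, i, f"{rho.values[i, j]:.2f}{mark}",
                        ha="center", va="center", fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="Spearman rho")
        return ax
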