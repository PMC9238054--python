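"""Replicate simulation studies: effect recovery and type-I error control.

These studies characterise the pipeline as an instrument: does it recover
the sign structure of a programmed irradiation effect at cohort scale, and
does the paired test hold its nominal false-positive rate when no effect
exists?  They run on reduced frames whose geometry (disc size, vessel
calibre, background correlation length and superpixel pitch) is rescaled
proportionally, so the scan composition matches the full 750 x 360 frame
while hundreds of cohorts stay affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CohortFlowModel
from .peripapillary import compute_mv_mt, make_annulus
from .stats import average_scans, paired_t
from .synthetic import CohortGeometry, EffectModel, generate_cohort, to_cohort_patients

__all__ = ["RecoveryStudy", "recovery_study", "type_i_error_study"]

#: Default reduced frame: 1/5.6 linear scale of the full sensor.
STUDY_SHAPE = (64, 128)


@dataclass(frozen=True)
class RecoveryStudy:
    """Replicate-level success rates of the paired-eye analysis."""

    n_replicates: int
    n_patients: int
    paired_rate: float  # replicates with all four paired effects significant
    slope_rate: float  # replicates with both irradiated slope signs correct
    joint_rate: float  # both of the above at once
    fellow_nonsig_rate: dict[str, float]  # per measure, fraction with p > 0.05


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def recovery_study(
    n_replicates: int = 100,
    n_patients: int = 25,
    effect: EffectModel | None = None,
    shape: tuple[int, int] = STUDY_SHAPE,
    seed: int = 0,
    alpha: float = 0.05,
) -> RecoveryStudy:
    """Re-run the full pipeline on many simulated cohorts.

    A replicate counts as a paired-test success when MV, MT and the
    percent of superpixels at >= 20 AU are significantly lower, and the
    percent at < 5 AU significantly higher, in irradiated than fellow eyes
    (two-tailed p < alpha with the correct sign); as a slope success when
    the irradiated-eye regression on time from treatment is negative for
    pct_ge20 and positive for pct_lt5.  Fellow-eye non-significance rates
    should sit near 1 - alpha, since fellow measures do not depend on time.
    """
    effect = effect or EffectModel()
    geometry = CohortGeometry.for_shape(shape)
    n_sp = geometry.matched_n_superpixels()
    lower = ("mv", "mt", "pct_ge20")
    fellow_measures = ("mv", "mt", "pct_ge20", "pct_lt5")
    paired_ok = slope_ok = joint_ok = 0
    fellow_nonsig = {m: 0 for m in fellow_measures}
    for rep_seed in _replicate_seeds(seed, n_replicates):
        entries = generate_cohort(n_patients, effect, seed=rep_seed, geometry=geometry)
        model = CohortFlowModel.from_cohort(
            to_cohort_patients(entries, geometry), n_superpixels=n_sp
        )
        results = model.fit()
        pt = results.paired_tests.set_index("measure")
        p_ok = all(
            pt.loc[m, "p_value"] < alpha and pt.loc[m, "t"] < 0 for m in lower
        ) and (pt.loc["pct_lt5", "p_value"] < alpha and pt.loc["pct_lt5", "t"] > 0)
        reg = results.regressions.set_index(["measure", "group"])
        s_ok = (
            reg.loc[("pct_ge20", "irradiated"), "slope"] < 0
            and reg.loc[("pct_lt5", "irradiated"), "slope"] > 0
        )
        paired_ok += p_ok
        slope_ok += s_ok
        joint_ok += p_ok and s_ok
        for m in fellow_measures:
            fellow_nonsig[m] += reg.loc[(m, "fellow"), "p_value"] > alpha
    return RecoveryStudy(
        n_replicates=n_replicates,
        n_patients=n_patients,
        paired_rate=paired_ok / n_replicates,
        slope_rate=slope_ok / n_replicates,
        joint_rate=joint_ok / n_replicates,
        fellow_nonsig_rate={m: v / n_replicates for m, v in fellow_nonsig.items()},
    )


def type_i_error_study(
    n_replicates: int = 400,
    n_patients: int = 10,
    shape: tuple[int, int] = STUDY_SHAPE,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Paired-test rejection rate on null cohorts (no irradiation effect).

    Cohorts are generated with ``k_per_month = 0`` so the two eyes differ
    only by independent anatomy and scan noise; the per-eye measure is the
    three-scan mean of the annulus tissue flow MT, whose paired differences
    are close to normal under the null (MV is unsuitable here: small
    anatomy-driven jumps of the vessel/tissue threshold give its null
    differences heavy tails, for which the t-test is conservative).
    Returns the fraction of replicates with two-tailed p < alpha, which
    should match alpha up to binomial noise.
    """
    null_effect = EffectModel(k_per_month=0.0, m_min=1.0)
    geometry = CohortGeometry.for_shape(shape)
    annulus = make_annulus(geometry.center(), geometry.disc_radius, geometry.shape)
    rejections = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        entries = generate_cohort(n_patients, null_effect, seed=rep_seed,
                                  geometry=geometry)
        irr, fellow = [], []
        for spec, scans in entries:
            mt = {"OD": [], "OS": []}
            for scan in scans:
                mt[scan.eye].append(compute_mv_mt(scan, annulus).mt)
            fellow_eye = "OS" if spec.irradiated_eye == "OD" else "OD"
            irr.append(average_scans(mt[spec.irradiated_eye]))
            fellow.append(average_scans(mt[fellow_eye]))
        rejections += paired_t(irr, fellow).p_value < alpha
    return rejections / n_replicates
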