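"""Concentration-response pharmacology: Hill fits, curation, normalization, calls.

Each biological replicate of a 12-point concentration-response curve is fitted
separately to a Hill equation with the slope fixed at 1.  The BRET sensor used
for Gs activation *decreases* upon receptor activation, so the pre-transition
(low-concentration) baseline lies above the post-transition baseline; the
signal amplitude is reported as the positive magnitude |pre - post|.

Mutant amplitudes are normalized to batch-matched wild-type amplitudes (to
correct day-to-day variation), while mutant logEC50 values are normalized to
the mean wild-type logEC50 across the whole screen.  Cut-offs applied to the
normalized values discretize each mutant into a pharmacology call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "DoseResponseReplicate",
    "HillFit",
    "PharmacologyCutoffs",
    "MutantPharmProfile",
    "fit_hill",
    "curate_replicates",
    "normalize_profile",
    "classify_pharmacology",
    "process_screen",
    "hill_curve",
    "CONC_GRID",
]

#: Default 12-point measurement grid, log10 molar: 11 half-log agonist
#: concentrations from 1e-8.5 to 1e-3.5 M plus the vehicle (zero-agonist)
#: well, represented as a far-sub-threshold point two log units below the
#: lowest concentration.
CONC_GRID = np.concatenate([[-10.5], np.arange(-8.5, -3.4, 0.5)])

#: Calls that count as pharmacologically important downstream.
IMPORTANT_CALLS = frozenset(
    {"efficacy_reduced", "potency_reduced", "both_reduced", "no_signal"}
)


@dataclass(frozen=True)
class DoseResponseReplicate:
    """One biological replicate: raw BRET ratio vs log10 agonist concentration."""

    mutant_id: str
    replicate_id: str
    batch_id: str
    log_conc: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        lc = np.asarray(self.log_conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "log_conc", lc)
        object.__setattr__(self, "response", resp)
        if lc.shape != resp.shape or lc.ndim != 1:
            raise ValueError(
                f"{self.mutant_id}/{self.replicate_id}: log_conc and response "
                "must be 1-D arrays of equal length"
            )
        if len(lc) < 6:
            raise ValueError(
                f"{self.mutant_id}/{self.replicate_id}: at least 6 points are "
                f"required for fitting, got {len(lc)}"
            )
        if not np.all(np.diff(lc) > 0):
            raise ValueError(
                f"{self.mutant_id}/{self.replicate_id}: log_conc must be "
                "strictly increasing"
            )
        if not np.all(np.isfinite(resp)):
            raise ValueError(
                f"{self.mutant_id}/{self.replicate_id}: non-finite response values"
            )


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters for one replicate (slope fixed at 1)."""

    mutant_id: str
    replicate_id: str
    batch_id: str
    logec50: float
    baseline_pre: float
    baseline_post: float
    status: str  # ok | unfittable | excluded_curation

    @property
    def amplitude(self) -> float:
        """Signal amplitude as a positive magnitude (raw BRET)."""
        return abs(self.baseline_pre - self.baseline_post)


@dataclass(frozen=True)
class PharmacologyCutoffs:
    """Discretization thresholds on the normalized pharmacology scales.

    The loss cut-offs correspond to two wild-type standard deviations on the
    normalized amplitude and a 7.4-fold potency shift; mutants expressing
    below ``abundance_min`` percent of wild type are excluded, and curves
    whose fitted baseline gap falls below ``min_raw_amplitude`` raw BRET are
    unfittable.
    """

    amplitude_loss: float = 0.74
    potency_loss: float = 0.87
    amplitude_gain: float = 1.28
    potency_gain: float = -0.71
    abundance_min: float = 25.0
    min_raw_amplitude: float = 0.015

    def __post_init__(self):
        if not (self.amplitude_loss < 1.0 < self.amplitude_gain):
            raise ValueError("require amplitude_loss < 1 < amplitude_gain")
        if not (self.potency_gain < 0.0 < self.potency_loss):
            raise ValueError("require potency_gain < 0 < potency_loss")


@dataclass
class MutantPharmProfile:
    """Normalized, discretized pharmacology of one mutant."""

    mutant_id: str
    n_replicates: int
    norm_amplitude: float  # WT = 1; NaN when no fittable replicate
    delta_logec50: float  # mutant - mean WT; positive = potency loss; NaN if none
    abundance_pct: float
    call: str | None = None
    #: set when a loss cut-off and a gain cut-off are crossed simultaneously
    conflict_flag: bool = False
    curation_note: str = ""


def hill_curve(
    log_conc: np.ndarray, logec50: float, pre: float, post: float
) -> np.ndarray:
    """Hill equation with slope 1 in log10 concentration.

    ``pre`` is the low-concentration (pre-transition) baseline and ``post``
    the saturating plateau; the curve transitions monotonically between them
    with half-maximal response at ``logec50``.
    """
    log_conc = np.asarray(log_conc, dtype=float)
    return pre + (post - pre) / (1.0 + 10.0 ** (logec50 - log_conc))


def fit_hill(
    replicate: DoseResponseReplicate,
    min_raw_amplitude: float = 0.015,
) -> HillFit:
    """Least-squares Hill fit (slope fixed at 1) of a single replicate.

    Returns status ``unfittable`` when the optimizer fails, the fitted
    baseline gap |pre - post| is below ``min_raw_amplitude``, or the fitted
    logEC50 falls more than one log unit outside the measured range.
    """
    lc, resp = replicate.log_conc, replicate.response

    n_edge = max(2, len(lc) // 4)
    pre0 = float(np.mean(resp[:n_edge]))
    post0 = float(np.mean(resp[-n_edge:]))
    ec0 = float(np.median(lc))

    def _unfittable() -> HillFit:
        return HillFit(
            replicate.mutant_id,
            replicate.replicate_id,
            replicate.batch_id,
            math.nan,
            math.nan,
            math.nan,
            "unfittable",
        )

    try:
        with warnings.catch_warnings():
            # flat curves legitimately yield unestimable covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                hill_curve,
                lc,
                resp,
                p0=[ec0, pre0, post0],
                maxfev=10000,
                xtol=1e-12,
                ftol=1e-12,
            )
    except (RuntimeError, ValueError):
        return _unfittable()

    logec50, pre, post = (float(v) for v in popt)
    if abs(pre - post) < min_raw_amplitude:
        return _unfittable()
    if not (lc[0] - 1.0 <= logec50 <= lc[-1] + 1.0):
        return _unfittable()
    return HillFit(
        replicate.mutant_id,
        replicate.replicate_id,
        replicate.batch_id,
        logec50,
        pre,
        post,
        "ok",
    )


def curate_replicates(
    fits: list[HillFit], qc_failed: set[str] | None = None
) -> list[HillFit]:
    """Mark whole replicates flagged by QC as excluded; never drop single points.

    ``qc_failed`` holds replicate_ids whose experiment visibly failed (bad
    transfection, unfittable noise).  Order is preserved; retained fits are
    returned unchanged.
    """
    qc_failed = qc_failed or set()
    out = []
    for f in fits:
        if f.replicate_id in qc_failed:
            out.append(replace(f, status="excluded_curation"))
        else:
            out.append(f)
    return out


def normalize_profile(
    mutant_fits: list[HillFit],
    wt_reference: list[HillFit],
    wt_global: list[HillFit],
    abundance_pct: float,
) -> MutantPharmProfile:
    """Normalize one mutant's fitted parameters against wild type.

    Amplitude is normalized to the mean of the batch-matched wild-type fits
    (``wt_reference``); logEC50 is normalized to the mean over all wild-type
    fits in the screen (``wt_global``).  No abundance correction is applied.
    A mutant with zero fittable replicates yields NaN parameters and is a
    ``no_signal`` candidate for classification.
    """
    ok = [f for f in mutant_fits if f.status == "ok"]
    wt_ref_ok = [f for f in wt_reference if f.status == "ok"]
    wt_glob_ok = [f for f in wt_global if f.status == "ok"]
    if not mutant_fits:
        raise ValueError("no fits supplied for mutant")
    mutant_id = mutant_fits[0].mutant_id
    if not wt_ref_ok:
        batches = sorted({f.batch_id for f in mutant_fits})
        raise ValueError(
            f"no wild-type reference fits for batch(es) {batches} "
            f"needed by mutant {mutant_id}"
        )
    if not wt_glob_ok:
        raise ValueError("no wild-type fits in the global reference set")

    if not ok:
        return MutantPharmProfile(
            mutant_id=mutant_id,
            n_replicates=0,
            norm_amplitude=math.nan,
            delta_logec50=math.nan,
            abundance_pct=abundance_pct,
            curation_note="no fittable replicate",
        )

    norm_amp = float(
        np.mean([f.amplitude for f in ok]) / np.mean([f.amplitude for f in wt_ref_ok])
    )
    dlog = float(
        np.mean([f.logec50 for f in ok]) - np.mean([f.logec50 for f in wt_glob_ok])
    )
    return MutantPharmProfile(
        mutant_id=mutant_id,
        n_replicates=len(ok),
        norm_amplitude=norm_amp,
        delta_logec50=dlog,
        abundance_pct=abundance_pct,
    )


def classify_pharmacology(
    profile: MutantPharmProfile, cutoffs: PharmacologyCutoffs | None = None
) -> MutantPharmProfile:
    """Assign the discretized pharmacology call for a normalized profile.

    Low abundance dominates everything; then the no-signal path; then the
    loss conditions (strict inequalities exactly at the printed cut-offs,
    equality counting as wild-type-like); a gain call only applies when no
    loss condition holds.  When a loss cut-off and a gain cut-off are crossed
    on opposite parameters, the loss call wins and ``conflict_flag`` is set.
    """
    c = cutoffs or PharmacologyCutoffs()
    p = replace(profile)
    if p.abundance_pct < c.abundance_min:
        p.call = "excluded_low_abundance"
        return p
    if p.n_replicates == 0 or not np.isfinite(p.norm_amplitude):
        p.call = "no_signal"
        return p

    eff_loss = p.norm_amplitude < c.amplitude_loss
    pot_loss = p.delta_logec50 > c.potency_loss
    eff_gain = p.norm_amplitude > c.amplitude_gain
    pot_gain = p.delta_logec50 < c.potency_gain

    if eff_loss and pot_loss:
        p.call = "both_reduced"
    elif eff_loss:
        p.call = "efficacy_reduced"
        p.conflict_flag = pot_gain
    elif pot_loss:
        p.call = "potency_reduced"
        p.conflict_flag = eff_gain
    elif eff_gain or pot_gain:
        p.call = "gain_of_function"
    else:
        p.call = "wild_type_like"
    return p


def _replicates_from_frame(curves: pd.DataFrame) -> list[DoseResponseReplicate]:
    required = {"mutant_id", "replicate_id", "batch_id", "log_conc", "response"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table missing columns: {sorted(missing)}")
    reps = []
    for (mid, rid, bid), grp in curves.groupby(
        ["mutant_id", "replicate_id", "batch_id"], sort=True
    ):
        grp = grp.sort_values("log_conc")
        reps.append(
            DoseResponseReplicate(
                str(mid),
                str(rid),
                str(bid),
                grp["log_conc"].to_numpy(),
                grp["response"].to_numpy(),
            )
        )
    return reps


def process_screen(
    curves: pd.DataFrame,
    abundance: pd.DataFrame,
    cutoffs: PharmacologyCutoffs | None = None,
    qc_failed: set[str] | None = None,
    wt_id: str = "WT",
) -> pd.DataFrame:
    """Run the full pharmacology stage on a tidy screen table.

    ``curves`` has one row per mutant x replicate x concentration with columns
    mutant_id, replicate_id, batch_id, log_conc, response; ``abundance`` has
    mutant_id, abundance_pct.  Returns one row per mutant (wild-type control
    rows excluded) with the normalized parameters and the call.
    """
    cutoffs = cutoffs or PharmacologyCutoffs()
    reps = _replicates_from_frame(curves)
    fits = [fit_hill(r, cutoffs.min_raw_amplitude) for r in reps]
    fits = curate_replicates(fits, qc_failed)

    by_mutant: dict[str, list[HillFit]] = {}
    for f in fits:
        by_mutant.setdefault(f.mutant_id, []).append(f)

    wt_fits = by_mutant.get(wt_id, [])
    if not any(f.status == "ok" for f in wt_fits):
        raise ValueError(f"no usable wild-type ('{wt_id}') fits in the screen")
    wt_by_batch: dict[str, list[HillFit]] = {}
    for f in wt_fits:
        wt_by_batch.setdefault(f.batch_id, []).append(f)

    abund = abundance.set_index(abundance["mutant_id"].astype(str))["abundance_pct"]

    rows = []
    for mid in sorted(by_mutant):
        if mid == wt_id:
            continue
        mfits = by_mutant[mid]
        if mid not in abund.index:
            raise ValueError(f"mutant {mid} has no abundance entry")
        batches = {f.batch_id for f in mfits}
        wt_ref = [f for b in sorted(batches) for f in wt_by_batch.get(b, [])]
        profile = normalize_profile(mfits, wt_ref, wt_fits, float(abund[mid]))
        profile = classify_pharmacology(profile, cutoffs)
        rows.append(
            {
                "mutant_id": mid,
                "n_replicates": profile.n_replicates,
                "norm_amplitude": profile.norm_amplitude,
                "delta_logec50": profile.delta_logec50,
                "abundance_pct": profile.abundance_pct,
                "call": profile.call,
                "conflict_flag": profile.conflict_flag,
                "curation_note": profile.curation_note,
            }
        )
    return pd.DataFrame(rows)
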