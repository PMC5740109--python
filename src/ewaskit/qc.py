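"""Quality control and normalization for array methylation data.

Covers detection p-values against a designated background probe set,
probe and sample filtering with fully reconciled accounting, sex
prediction from Y-probe methylation, stratified quantile normalization,
the beta transform, and reference-based cell-type deconvolution
(constrained least squares onto purified leukocyte profiles).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import CELL_TYPES, CellReference

DEFAULT_DETECTION_THRESHOLD = 1e-12
DEFAULT_CALL_RATE = 0.98

#: Absolute fallback thresholds for sex calling when the cohort contains a
#: single cluster (one-sex cohorts): mean Y-probe beta in [MALE_Y_MIN,
#: MALE_Y_MAX] is called male, below MALE_Y_MIN female.
MALE_Y_MIN = 0.2
MALE_Y_MAX = 0.8


# ---------------------------------------------------------------------------
# Detection p-values and filtering
# ---------------------------------------------------------------------------


def compute_detection_p(
    intensities: pd.DataFrame, background_probe_ids: list[str] | pd.Index
) -> pd.DataFrame:
    """Upper-tail detection p-value per (probe, sample).

    For each sample, a normal background is estimated from the designated
    background probes (mean and SD of their intensities in that sample) and
    every probe's p-value is the upper-tail probability of its intensity
    under that background.  Well-measured probes sit far above background
    and get vanishing p; the conventional pass threshold is p < 1e-12.
    """
    bg = [p for p in background_probe_ids if p in intensities.index]
    if len(bg) < 2:
        raise ValueError("need at least 2 background probes present in the matrix")
    if len(bg) < 10:
        warnings.warn(
            f"only {len(bg)} background probes; detection p-values will be noisy",
            stacklevel=2,
        )
    if (intensities.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    mu = intensities.loc[bg].mean(axis=0)
    sd = intensities.loc[bg].std(axis=0, ddof=1).replace(0.0, np.nan)
    z = (intensities - mu) / sd
    p = pd.DataFrame(
        stats.norm.sf(z.to_numpy()), index=intensities.index, columns=intensities.columns
    )
    return p.fillna(1.0)


@dataclasses.dataclass
class FilterReport:
    """Reconciled probe/sample filtering accounting.

    Each probe is counted under exactly one removal reason, applied in the
    documented precedence order control -> sex chromosome -> SNP proximity
    -> detection failure.
    """

    n_input_probes: int
    n_removed_control: int
    n_removed_sex: int
    n_removed_snp: int
    n_removed_detection: int
    n_retained: int
    removed_samples: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_control
            + self.n_removed_sex
            + self.n_removed_snp
            + self.n_removed_detection
            + self.n_retained
        )
        if total != self.n_input_probes:
            raise ValueError("filter report does not reconcile")


def filter_probes(
    manifest: pd.DataFrame,
    detection: pd.DataFrame | None = None,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    max_fail_fraction: float = 0.05,
) -> tuple[pd.Index, FilterReport]:
    """Remove control, sex-chromosome, SNP-proximal and undetected probes.

    Removal precedence is control -> sex -> SNP -> detection so every probe
    has exactly one removal reason and the report reconciles to the input
    count.  A probe fails detection when its p >= ``threshold`` in more
    than ``max_fail_fraction`` of samples.
    """
    probes = detection.index if detection is not None else manifest["probe_id"]
    ann = manifest.set_index("probe_id")
    missing = [p for p in probes if p not in ann.index]
    if missing:
        raise ValueError(f"manifest does not cover probes: {missing[:3]} ...")
    ann = ann.loc[probes]

    is_control = ann["is_control"].to_numpy(bool)
    on_sex = ann["chromosome"].isin(["X", "Y"]).to_numpy() & ~is_control
    snp = ann["snp_within_10bp"].to_numpy(bool) & ~is_control & ~on_sex
    if detection is not None:
        fail_frac = (detection.to_numpy() >= threshold).mean(axis=1)
        det_fail = (fail_frac > max_fail_fraction) & ~is_control & ~on_sex & ~snp
    else:
        det_fail = np.zeros(len(ann), dtype=bool)

    keep = ~(is_control | on_sex | snp | det_fail)
    retained = pd.Index(np.asarray(probes)[keep])
    if len(retained) == 0:
        raise ValueError("all probes removed by filtering")
    report = FilterReport(
        n_input_probes=len(ann),
        n_removed_control=int(is_control.sum()),
        n_removed_sex=int(on_sex.sum()),
        n_removed_snp=int(snp.sum()),
        n_removed_detection=int(det_fail.sum()),
        n_retained=len(retained),
    )
    return retained, report


def filter_samples(
    detection: pd.DataFrame,
    call_rate_threshold: float = DEFAULT_CALL_RATE,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> tuple[list[str], dict[str, str]]:
    """Drop samples whose call rate is strictly below the threshold.

    Call rate is the fraction of probes detected (p < detection threshold)
    in the sample; a sample at exactly the threshold is retained.
    """
    call_rate = (detection < detection_threshold).mean(axis=0)
    removed = {
        s: f"call rate {call_rate[s]:.4f} < {call_rate_threshold}"
        for s in detection.columns
        if call_rate[s] < call_rate_threshold
    }
    retained = [s for s in detection.columns if s not in removed]
    if not retained:
        raise ValueError("all samples removed by call-rate filtering")
    return retained, removed


# ---------------------------------------------------------------------------
# Sex prediction
# ---------------------------------------------------------------------------


def predict_sex(
    beta: pd.DataFrame, manifest: pd.DataFrame, samples: pd.DataFrame | None = None
) -> tuple[pd.Series, list[str]]:
    """Call sample sex from mean Y-probe methylation.

    Males retain intermediate Y-probe beta; females show only background.
    With both sexes present a 1-D two-means split separates the clusters;
    one-cluster cohorts fall back to absolute thresholds (see
    :data:`MALE_Y_MIN`).  Returns per-sample calls plus the list of samples
    mismatching ``self_reported_sex`` (flagged, not auto-dropped).
    """
    ann = manifest.set_index("probe_id")
    y_probes = [p for p in beta.index if p in ann.index and ann.loc[p, "chromosome"] == "Y"]
    x_probes = [p for p in beta.index if p in ann.index and ann.loc[p, "chromosome"] == "X"]
    if not y_probes or not x_probes:
        raise ValueError("need at least one X and one Y probe to predict sex")
    y_mean = beta.loc[y_probes].mean(axis=0)

    if len(y_mean) < 2:
        warnings.warn("cannot cluster a single sample; calling indeterminate", stacklevel=2)
        calls = pd.Series("indeterminate", index=beta.columns, name="predicted_sex")
        return calls, []

    # 1-D two-means: split at the midpoint of the two cluster centers,
    # iterated to a fixed point; degenerate (one-cluster) cohorts use the
    # absolute thresholds instead.
    v = y_mean.to_numpy()
    lo, hi = v.min(), v.max()
    if hi - lo < 0.1:  # single cluster: one-sex cohort
        center = float(np.mean(v))
        if MALE_Y_MIN <= center <= MALE_Y_MAX:
            calls = pd.Series("male", index=y_mean.index)
        elif center < MALE_Y_MIN:
            calls = pd.Series("female", index=y_mean.index)
        else:
            calls = pd.Series("indeterminate", index=y_mean.index)
    else:
        c0, c1 = lo, hi
        for _ in range(50):
            assign = np.abs(v - c0) <= np.abs(v - c1)
            n0, n1 = float(v[assign].mean()), float(v[~assign].mean())
            if (n0, n1) == (c0, c1):
                break
            c0, c1 = n0, n1
        low_cluster = assign if c0 < c1 else ~assign
        calls = pd.Series(np.where(low_cluster, "female", "male"), index=y_mean.index)
    calls.name = "predicted_sex"
    mismatches = sex_mismatches(calls, samples) if samples is not None else []
    return calls, mismatches


def sex_mismatches(calls: pd.Series, samples: pd.DataFrame) -> list[str]:
    """Samples whose predicted sex contradicts the self-reported sex."""
    out = []
    for s, call in calls.items():
        reported = samples.loc[s, "self_reported_sex"] if s in samples.index else None
        if reported is not None and call != "indeterminate" and call != reported:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Normalization and the beta transform
# ---------------------------------------------------------------------------


def quantile_normalize(
    intensities: pd.DataFrame, strata: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Quantile-normalize sample columns within probe strata.

    Within each stratum every sample's sorted values are mapped onto the
    across-sample mean of the sorted values, making the per-sample
    distributions identical (ties resolved by average ranks).  ``strata``
    maps stratum name to probe ids and must partition the rows; the default
    is a single stratum.
    """
    if strata is None:
        strata = {"all": list(intensities.index)}
    covered = [p for ids in strata.values() for p in ids]
    if sorted(covered) != sorted(intensities.index):
        raise ValueError("strata must partition the probe set exactly")
    out = intensities.copy().astype(float)
    for name, ids in strata.items():
        block = intensities.loc[ids].to_numpy(float)
        if block.shape[0] == 1:
            warnings.warn(f"stratum {name!r} has a single probe; passthrough", stacklevel=2)
            continue
        ref = np.sort(block, axis=0).mean(axis=1)
        ranks = np.apply_along_axis(stats.rankdata, 0, block)  # average ties
        norm = np.interp(ranks, np.arange(1, block.shape[0] + 1), ref)
        out.loc[ids] = norm
    return out


def beta_from_intensity(
    meth: pd.DataFrame, unmeth: pd.DataFrame, offset: float = 100.0
) -> pd.DataFrame:
    """beta = M / (M + U + offset); the offset regularizes dim probes."""
    if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    return meth / (meth + unmeth + offset)


# ---------------------------------------------------------------------------
# Cell-type deconvolution
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CellProportions:
    """Estimated leukocyte fractions per sample plus fit residual norms."""

    fractions: pd.DataFrame  # samples x CELL_TYPES
    residual_norm: pd.Series


def estimate_cell_proportions(
    beta: pd.DataFrame, reference: CellReference, sum_to_one: bool = False
) -> CellProportions:
    """Reference-based deconvolution by constrained least squares.

    Per sample, solves ``min ||beta_markers - R w||^2`` subject to
    ``w >= 0`` and ``sum(w) <= 1`` (or ``= 1`` when ``sum_to_one``).  The
    inequality default reflects that measured whole-blood fractions need
    not exhaust the sample.  Only marker probes participate, so the result
    is invariant to adding non-marker probes.
    """
    markers = [p for p in reference.marker_probes if p in beta.index]
    frac_missing = 1 - len(markers) / len(reference.marker_probes)
    if frac_missing > 0.2:
        raise ValueError(
            f"{frac_missing:.0%} of reference marker probes missing from beta"
        )
    R = reference.profiles.loc[markers].to_numpy()
    Y = beta.loc[markers].to_numpy()
    k = R.shape[1]
    rows, resids = [], []
    cons = (
        {"type": "eq", "fun": lambda w: w.sum() - 1.0}
        if sum_to_one
        else {"type": "ineq", "fun": lambda w: 1.0 - w.sum()}
    )
    for j in range(Y.shape[1]):
        y = Y[:, j]
        w0, _ = optimize.nnls(R, y)
        if sum_to_one or w0.sum() > 1.0:
            res = optimize.minimize(
                lambda w: 0.5 * np.sum((R @ w - y) ** 2),
                x0=np.clip(w0, 0, None) / max(w0.sum(), 1.0),
                jac=lambda w: R.T @ (R @ w - y),
                bounds=[(0.0, 1.0)] * k,
                constraints=[cons],
                method="SLSQP",
                options={"maxiter": 200, "ftol": 1e-12},
            )
            w0 = res.x
        rows.append(w0)
        resids.append(float(np.linalg.norm(R @ w0 - y)))
    fractions = pd.DataFrame(rows, index=beta.columns, columns=list(CELL_TYPES))
    return CellProportions(
        fractions=fractions,
        residual_norm=pd.Series(resids, index=beta.columns, name="residual_norm"),
    )
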