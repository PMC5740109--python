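"""Fixed-effect meta-analysis of per-probe association results.

Two pooling schemes, mirroring standard genome-wide meta-analysis
practice: inverse-variance weighting of coefficients (the default when
coefficients and SEs are available) and sample-size-weighted combination
of signed z-scores.  Cochran's Q and the I^2 statistic quantify
between-study heterogeneity.  Probes are aligned by id; probes present in
only one study are reported separately rather than silently pooled —
different array generations share only part of their probe sets.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import adjust_fdr

REQUIRED_COLUMNS = ("coefficient", "se", "p", "n")


def _validate(study: pd.DataFrame) -> None:
    for c in REQUIRED_COLUMNS:
        if c not in study.columns:
            raise ValueError(f"study table missing column {c!r}")
    if (study["se"] <= 0).any():
        raise ValueError("study SEs must be positive")


def _direction_string(coefs: list[float]) -> str:
    return "".join("+" if c > 0 else "-" if c < 0 else "0" for c in coefs)


def inverse_variance_meta(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effect pooling over shared probes.

    Per probe, weights w_i = 1/SE_i^2 give pooled coefficient
    sum(w b)/sum(w), pooled SE 1/sqrt(sum w), z = coef/SE and a two-sided
    normal p.  Returns a table indexed by probe id with pooled statistics,
    Q, I^2 (percent), the study count k, a +/- direction string and a BH q
    over the pooled probes.  Probes present in a single study are included
    with ``unpooled=True`` and their own statistics passed through.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    for s in studies:
        _validate(s)
    all_probes = pd.Index(sorted(set().union(*[set(s.index) for s in studies])))
    rows = []
    for pid in all_probes:
        present = [s.loc[pid] for s in studies if pid in s.index]
        b = np.array([r["coefficient"] for r in present], float)
        se = np.array([r["se"] for r in present], float)
        k = len(present)
        if k == 1:
            rows.append(
                {
                    "probe_id": pid,
                    "coefficient": b[0],
                    "se": se[0],
                    "z": b[0] / se[0],
                    "p": float(present[0]["p"]),
                    "Q": np.nan,
                    "I2": np.nan,
                    "k": 1,
                    "direction": _direction_string(list(b)),
                    "unpooled": True,
                }
            )
            continue
        w = 1.0 / se**2
        coef = float(np.sum(w * b) / np.sum(w))
        pooled_se = float(1.0 / np.sqrt(np.sum(w)))
        z = coef / pooled_se
        Q = float(np.sum(w * (b - coef) ** 2))
        i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
        rows.append(
            {
                "probe_id": pid,
                "coefficient": coef,
                "se": pooled_se,
                "z": z,
                "p": float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0)),
                "Q": Q,
                "I2": i2,
                "k": k,
                "direction": _direction_string(list(b)),
                "unpooled": False,
            }
        )
    out = pd.DataFrame(rows).set_index("probe_id")
    pooled = out.index[~out["unpooled"]]
    out["q"] = np.nan
    if len(pooled):
        out.loc[pooled, "q"] = adjust_fdr(out.loc[pooled, "p"].to_numpy())
    return out


def sample_size_meta(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size-weighted z-score pooling over shared probes.

    Per study, z_i = sign(coefficient) * Phi^{-1}(1 - p_i/2); the pooled
    statistic is Z = sum(sqrt(n_i) z_i) / sqrt(sum n_i) with a two-sided
    normal p.  Input p-values of exactly 0 are clipped to the smallest
    positive double with a warning.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    for s in studies:
        _validate(s)
    shared = set(studies[0].index)
    for s in studies[1:]:
        shared &= set(s.index)
    rows = []
    tiny = np.finfo(float).tiny
    clipped = False
    for pid in sorted(shared):
        zs, ns, signs = [], [], []
        for s in studies:
            r = s.loc[pid]
            p = float(r["p"])
            if p <= 0:
                p, clipped = tiny, True
            z = stats.norm.isf(p / 2.0)
            sign = 1.0 if r["coefficient"] > 0 else -1.0 if r["coefficient"] < 0 else 0.0
            zs.append(sign * z)
            ns.append(float(r["n"]))
            signs.append(sign)
        Z = float(np.sum(np.sqrt(ns) * np.asarray(zs)) / np.sqrt(np.sum(ns)))
        rows.append(
            {
                "probe_id": pid,
                "z": Z,
                "p": float(np.clip(2 * stats.norm.sf(abs(Z)), tiny, 1.0)),
                "direction": "".join("+" if s > 0 else "-" if s < 0 else "0" for s in signs),
            }
        )
    if clipped:
        warnings.warn("input p-values of 0 clipped to the smallest positive double", stacklevel=2)
    return pd.DataFrame(rows).set_index("probe_id")


def heterogeneity(coefficients: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Cochran's Q and I^2 (percent, floored at 0) for one probe."""
    b = np.asarray(coefficients, float)
    se = np.asarray(ses, float)
    if b.size < 2:
        raise ValueError("need at least two studies")
    if (se <= 0).any():
        raise ValueError("SEs must be positive")
    w = 1.0 / se**2
    pooled = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - pooled) ** 2))
    k = b.size
    i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return Q, i2


@dataclasses.dataclass
class ProbeOverlap:
    """Cross-study probe alignment report."""

    shared: list[str]
    only_in_one: dict[int, list[str]]  # study position -> private probe ids


def probe_overlap(studies: list[pd.DataFrame]) -> ProbeOverlap:
    """Report probes shared by all studies and probes private to one."""
    sets = [set(s.index) for s in studies]
    shared = set.intersection(*sets)
    only = {}
    for i, s in enumerate(sets):
        others = set().union(*[t for j, t in enumerate(sets) if j != i])
        private = s - others
        if private:
            only[i] = sorted(private)
    return ProbeOverlap(shared=sorted(shared), only_in_one=only)
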