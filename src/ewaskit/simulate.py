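"""Synthetic whole-blood methylation cohorts with known ground truth.

Generates array-style beta matrices as cell-type mixtures plus covariate,
batch and group effects, together with the side information a real study
ships with: a probe manifest, control-probe intensities, a sample covariate
table and (synthetic only) a truth block recording every injected signal.
The statistical structure mirrors what the downstream pipeline assumes:

* beta values are bounded in (0, 1) and bimodal (hypo/hemi/hyper baselines
  drawn on the logit scale);
* each sample is a Dirichlet mixture of six leukocyte reference profiles,
  so reference-based deconvolution is well posed;
* a per-sample batch factor loads on every probe *and* on the control-probe
  intensities, so control-probe PCA can recover and remove it;
* case/control effects are spiked at named probes and at contiguous
  gene-annotated probe runs (for region-level callers);
* a disease-burden index in [0, 120] is coupled, at a chosen correlation,
  to the weighted methylation burden over the spiked probes.

All randomness flows from a single ``numpy.random.default_rng(seed)``; the
same seed reproduces the same study bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import stats

# ---------------------------------------------------------------------------
# Constants: cell types and their population means (whole-blood fractions)
# ---------------------------------------------------------------------------

CELL_TYPES: tuple[str, ...] = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")

#: Mean leukocyte fractions used for the Dirichlet mixing distribution.
#: Granulocytes dominate whole blood; the Dirichlet concentration is chosen
#: so the granulocyte SD is ~0.13, typical of estimated compositions.
CELL_MEAN_FRACTIONS: dict[str, float] = {
    "CD4T": 0.03,
    "CD8T": 0.18,
    "NK": 0.07,
    "Bcell": 0.09,
    "Mono": 0.12,
    "Gran": 0.51,
}
DIRICHLET_CONCENTRATION = 14.0

REGION_CLASSES = ("TSS1500", "TSS200", "Body", "Island", "Intergenic")

CONTROL_CLASSES = (
    "STAINING",
    "EXTENSION",
    "HYBRIDIZATION",
    "BISULFITE_I",
    "BISULFITE_II",
    "SPECIFICITY",
    "NEGATIVE",
    "NORM_A",
    "NORM_T",
    "TARGET_REMOVAL",
)

#: Baseline raw intensity per control class (arbitrary fluorescence units).
_CONTROL_BASE = {
    "STAINING": 9000.0,
    "EXTENSION": 7000.0,
    "HYBRIDIZATION": 6000.0,
    "BISULFITE_I": 5000.0,
    "BISULFITE_II": 4500.0,
    "SPECIFICITY": 4000.0,
    "NEGATIVE": 500.0,
    "NORM_A": 3000.0,
    "NORM_T": 2800.0,
    "TARGET_REMOVAL": 2000.0,
}

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "gene",
    "region_class",
    "design_type",
    "snp_within_10bp",
    "is_control",
    "control_class",
]

_EPS = 1e-4  # clip margin keeping beta strictly inside (0, 1)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CellReference:
    """Expected beta per (marker probe x cell type) for six leukocyte types.

    ``profiles`` is a DataFrame indexed by marker probe id with one column
    per cell type in :data:`CELL_TYPES`.  Each marker is hypermethylated
    (~0.85) in its own type and hypomethylated (~0.15) elsewhere, giving a
    within-row cross-type contrast of at least 0.3 (identifiability).
    """

    profiles: pd.DataFrame

    @property
    def marker_probes(self) -> pd.Index:
        return self.profiles.index

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("reference beta values must lie in [0, 1]")


@dataclasses.dataclass
class SimTruth:
    """Ground truth for a synthetic study; absent for real data."""

    spike_probes: dict[str, float]  # probe_id -> delta beta (case - control)
    spike_regions: list[dict]  # gene, delta_beta, probe_ids, chrom, start, end
    cell_proportions: pd.DataFrame  # samples x CELL_TYPES
    batch: pd.Series  # per-sample batch factor
    burden: pd.Series  # spiked-burden score per sample
    score_index_r: float  # target burden-index correlation

    def to_json(self) -> str:
        payload = {
            "spike_probes": self.spike_probes,
            "spike_regions": self.spike_regions,
            "cell_proportions": self.cell_proportions.round(6).to_dict(orient="index"),
            "batch": self.batch.round(6).to_dict(),
            "burden": self.burden.round(8).to_dict(),
            "score_index_r": self.score_index_r,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


@dataclasses.dataclass
class MethylationStudy:
    """One cohort: matrices, manifest, covariates and (optionally) truth.

    ``beta``, ``intensity`` and ``control_intensities`` are DataFrames with
    probes as rows and sample ids as columns; ``samples`` is indexed by
    sample id and carries the covariate table.
    """

    beta: pd.DataFrame
    intensity: pd.DataFrame
    control_intensities: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        ids = list(self.samples.index)
        for name in ("beta", "intensity", "control_intensities"):
            mat = getattr(self, name)
            if list(mat.columns) != ids:
                raise ValueError(f"{name} columns do not match sample ids")
        if not np.isfinite(self.beta.to_numpy()).all():
            raise ValueError("beta contains non-finite values")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write study components as plain-text tables; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": outdir / "beta.tsv",
            "intensity": outdir / "intensity.tsv",
            "control_intensities": outdir / "control_intensities.tsv",
            "manifest": outdir / "manifest.tsv",
            "samples": outdir / "samples.csv",
        }
        fmt = "%.8g"
        self.beta.to_csv(paths["beta"], sep="\t", float_format=fmt)
        self.intensity.to_csv(paths["intensity"], sep="\t", float_format=fmt)
        self.control_intensities.to_csv(
            paths["control_intensities"], sep="\t", float_format=fmt
        )
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        self.samples.to_csv(paths["samples"], float_format=fmt)
        if self.truth is not None:
            paths["truth"] = outdir / "truth.json"
            paths["truth"].write_text(self.truth.to_json())
        return paths


# ---------------------------------------------------------------------------
# Manifest generation
# ---------------------------------------------------------------------------


def generate_manifest(
    n_autosomal: int,
    n_sex: int,
    n_snp_flagged: int,
    n_control: int,
    n_genes: int,
    seed: int,
) -> pd.DataFrame:
    """Build a probe-annotation manifest with gene-clustered autosomal probes.

    Parameters mirror the four probe categories a real array manifest mixes:
    plain autosomal probes (assigned to genes in runs of 3-10 consecutive
    positions 20-200 bp apart, so contiguous clusters exist for region
    callers), sex-chromosome probes, SNP-proximal flagged probes, and
    non-genomic control probes.  Total rows = sum of the four counts.
    """
    for name, v in (
        ("n_autosomal", n_autosomal),
        ("n_sex", n_sex),
        ("n_snp_flagged", n_snp_flagged),
        ("n_control", n_control),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    counter = 0
    chrom_cursor: dict[str, int] = {}

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"cg{counter:07d}"

    # --- autosomal gene runs -------------------------------------------------
    autosomes = [str(c) for c in range(1, 23)]
    gene_idx = 0
    assigned = 0
    run_chrom = 0
    while assigned < n_autosomal:
        chrom = autosomes[run_chrom % len(autosomes)]
        run_chrom += 1
        run_len = min(int(rng.integers(3, 11)), n_autosomal - assigned)
        gene = f"G{(gene_idx % n_genes) + 1:05d}"
        gene_idx += 1
        start = chrom_cursor.get(chrom, 0) + int(rng.integers(5_000, 20_000))
        pos = start
        for j in range(run_len):
            if j > 0:
                pos += int(rng.integers(20, 201))
            region = ("TSS1500", "TSS200")[j] if j < 2 else ("Body", "Island")[
                int(rng.integers(0, 2))
            ]
            design = "I" if rng.random() < 0.3 else "II"
            rows.append((next_id(), chrom, pos, gene, region, design, False, False, ""))
        chrom_cursor[chrom] = pos
        assigned += run_len

    # --- sex-chromosome probes ----------------------------------------------
    for j in range(n_sex):
        chrom = "X" if j % 2 == 0 else "Y"
        pos = chrom_cursor.get(chrom, 0) + int(rng.integers(5_000, 50_000))
        chrom_cursor[chrom] = pos
        design = "I" if rng.random() < 0.3 else "II"
        rows.append((next_id(), chrom, pos, "", "Intergenic", design, False, False, ""))

    # --- SNP-proximal flagged probes ----------------------------------------
    for _ in range(n_snp_flagged):
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        pos = chrom_cursor.get(chrom, 0) + int(rng.integers(5_000, 50_000))
        chrom_cursor[chrom] = pos
        design = "I" if rng.random() < 0.3 else "II"
        rows.append((next_id(), chrom, pos, "", "Intergenic", design, True, False, ""))

    # --- control probes (no genomic position requirement) --------------------
    for j in range(n_control):
        cls = CONTROL_CLASSES[j % len(CONTROL_CLASSES)]
        rows.append((f"ctl{j + 1:04d}", "", 1, "", "Intergenic", "II", False, True, cls))

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest["position"] = manifest["position"].astype(int)
    return manifest


def generate_cell_reference(n_marker_per_type: int, seed: int) -> CellReference:
    """Reference beta profiles for six leukocyte types.

    Each cell type gets ``n_marker_per_type`` marker probes with expected
    beta ~0.85 in that type and ~0.15 in the others (small uniform jitter),
    guaranteeing the >= 0.3 cross-type contrast deconvolution needs.
    """
    if n_marker_per_type < 1:
        raise ValueError("n_marker_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    index, blocks = [], []
    for ct in CELL_TYPES:
        for j in range(n_marker_per_type):
            index.append(f"cgmk_{ct}_{j + 1:03d}")
            row = 0.15 + rng.uniform(-0.03, 0.03, size=len(CELL_TYPES))
            row[CELL_TYPES.index(ct)] = 0.85 + rng.uniform(-0.03, 0.03)
            blocks.append(row)
    profiles = pd.DataFrame(blocks, index=index, columns=list(CELL_TYPES))
    return CellReference(profiles)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _marker_manifest(reference: CellReference) -> pd.DataFrame:
    """Annotation rows for reference marker probes (appended to a manifest)."""
    rows = []
    pos = 10_000_000
    for pid in reference.marker_probes:
        pos += 25_000
        rows.append((pid, "22", pos, "", "Intergenic", "II", False, False, ""))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _sample_covariates(rng: np.random.Generator, groups: np.ndarray) -> dict[str, np.ndarray]:
    """Nuisance covariates with realistic case/control contrasts.

    Cases are older and smoke/drink more (the confounding the regression
    model must absorb); viral load, adherence and WBC are matched.
    """
    case = groups == "case"
    n = len(groups)
    age = np.where(case, rng.normal(51.4, 4.8, n), rng.normal(47.0, 9.0, n))
    smoker = rng.random(n) < np.where(case, 0.70, 0.48)
    audit_c = np.clip(np.where(case, rng.normal(4.7, 3.7, n), rng.normal(3.0, 3.0, n)), 0, None)
    adherence = np.clip(rng.normal(0.75, 0.15, n), 0.0, 1.0)
    log10_vl = np.clip(np.where(case, rng.normal(2.6, 1.1, n), rng.normal(2.8, 1.3, n)), 0, None)
    wbc = np.clip(rng.normal(5.5, 1.8, n), 2.0, None)
    recency = np.where(
        case, np.where(rng.random(n) < 58 / 216, "current", "past"), "none"
    )
    return {
        "age": np.round(age, 1),
        "smoker": smoker.astype(int),
        "audit_c": np.round(audit_c, 1),
        "adherence": np.round(adherence, 3),
        "log10_vl": np.round(log10_vl, 2),
        "wbc": np.round(wbc, 2),
        "idu_recency": recency,
    }


def generate_cohort(
    manifest: pd.DataFrame,
    reference: CellReference,
    n_case: int,
    n_control: int,
    spike_probes: list[tuple[str, float]] | None = None,
    spike_regions: list[tuple[str, float]] | None = None,
    batch_sd: float = 1.0,
    batch_group_shift: float = 0.0,
    score_index_r: float = 0.0,
    noise_sd: float = 0.15,
    seed: int = 0,
    cohort_id: str = "cohort",
) -> MethylationStudy:
    """Simulate one case/control cohort with known truth.

    Beta at probe p, sample i is the inverse logit of::

        logit(mixture baseline) + age/smoking effects + l_p * b_i + noise

    plus the group effect ``delta_beta`` (added on the beta scale at spiked
    probes for cases, then clipped into (0, 1)).  The mixture baseline is
    ``sum_c w_ic * R[p, c]`` with ``w_i ~ Dirichlet`` and ``R`` the reference
    extended to all probes.  The per-sample batch factor ``b_i ~
    N(shift * case, batch_sd^2)`` also multiplies the control-probe
    intensities (``base * exp(0.3 b_i)``), so control-probe PCA can recover
    it; ``batch_group_shift`` > 0 makes the batch a genuine confounder.

    The frailty index is a clipped, rounded linear function of the
    standardized spiked-burden score with target correlation
    ``score_index_r``.
    """
    spike_probes = list(spike_probes or [])
    spike_regions = list(spike_regions or [])
    if not -1.0 <= score_index_r <= 1.0:
        raise ValueError("score_index_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)

    genomic = manifest.loc[~manifest["is_control"]].reset_index(drop=True)
    controls = manifest.loc[manifest["is_control"]].reset_index(drop=True)
    marker_ann = _marker_manifest(reference)
    overlap = set(genomic["probe_id"]) & set(marker_ann["probe_id"])
    if overlap:
        raise ValueError(f"manifest already contains marker probe ids: {sorted(overlap)[:3]}")
    full_genomic = pd.concat([genomic, marker_ann], ignore_index=True)
    probe_ids = full_genomic["probe_id"].to_numpy()
    n_probes = len(probe_ids)

    n = n_case + n_control
    sample_ids = [f"{cohort_id}_s{i + 1:04d}" for i in range(n)]
    groups = np.array(["case"] * n_case + ["control"] * n_control)

    # --- per-probe baselines: bimodal on the logit scale ---------------------
    mix_comp = rng.choice(3, size=n_probes, p=[0.35, 0.30, 0.35])
    base_logit = rng.normal(np.array([-2.2, 0.0, 2.2])[mix_comp], 0.4)
    # cell-type-sensitive probes: per-type logit offsets at 10% of probes
    ct_offsets = np.zeros((n_probes, len(CELL_TYPES)))
    sensitive = rng.random(n_probes) < 0.10
    ct_offsets[sensitive] = rng.normal(0.0, 0.5, size=(int(sensitive.sum()), len(CELL_TYPES)))

    # reference beta per probe x cell type
    ref_beta = expit(base_logit[:, None] + ct_offsets)
    is_marker = np.isin(probe_ids, reference.marker_probes)
    ref_beta[is_marker] = reference.profiles.loc[probe_ids[is_marker]].to_numpy()
    # Y probes: male-typical intermediate methylation
    on_y = (full_genomic["chromosome"] == "Y").to_numpy()
    ref_beta[on_y] = expit(rng.normal(0.0, 0.4, size=(int(on_y.sum()), 1)))

    # --- resolve spikes ------------------------------------------------------
    spike_delta = np.zeros(n_probes)
    pid_index = {p: k for k, p in enumerate(probe_ids)}
    truth_probes: dict[str, float] = {}
    for pid, delta in spike_probes:
        if pid not in pid_index:
            raise ValueError(f"spike probe not in manifest: {pid}")
        spike_delta[pid_index[pid]] += delta
        truth_probes[pid] = truth_probes.get(pid, 0.0) + delta
    truth_regions: list[dict] = []
    gene_col = full_genomic["gene"].to_numpy()
    for gene, delta in spike_regions:
        members = np.flatnonzero(gene_col == gene)
        if members.size == 0:
            raise ValueError(f"spike region gene not in manifest: {gene}")
        spike_delta[members] += delta
        sub = full_genomic.iloc[members].sort_values(["chromosome", "position"])
        # a gene label may recur on distant runs; record one truth region
        # per contiguous run so interval bookkeeping stays meaningful
        for chrom, chrom_sub in sub.groupby("chromosome"):
            pos = chrom_sub["position"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > 2000) + 1
            for seg in np.split(np.arange(len(pos)), breaks):
                run = chrom_sub.iloc[seg]
                truth_regions.append(
                    {
                        "gene": gene,
                        "delta_beta": delta,
                        "probe_ids": run["probe_id"].tolist(),
                        "chrom": str(chrom),
                        "start": int(run["position"].min()),
                        "end": int(run["position"].max()),
                    }
                )
        for pid in sub["probe_id"]:
            truth_probes[pid] = truth_probes.get(pid, 0.0) + delta
    # spiked probes get mid-range baselines so beta-scale shifts do not clip
    spiked_mask = spike_delta != 0
    if spiked_mask.any():
        mid = expit(rng.normal(0.0, 0.3, size=int(spiked_mask.sum())))
        ref_beta[spiked_mask] = mid[:, None]

    # --- per-sample structure -------------------------------------------------
    alpha = DIRICHLET_CONCENTRATION * np.array([CELL_MEAN_FRACTIONS[c] for c in CELL_TYPES])
    w = rng.dirichlet(alpha, size=n)  # n x 6
    batch = rng.normal(batch_group_shift * (groups == "case"), batch_sd if batch_sd > 0 else 0.0)

    cov = _sample_covariates(rng, groups)
    age_z = (cov["age"] - cov["age"].mean()) / max(cov["age"].std(), 1e-9)

    # --- assemble beta --------------------------------------------------------
    mixture = ref_beta @ w.T  # n_probes x n
    eta = logit(np.clip(mixture, _EPS, 1 - _EPS))
    covariate_probe = rng.random(n_probes) < 0.20
    age_load = np.where(covariate_probe, rng.normal(0.0, 0.05, n_probes), 0.0)
    smoke_load = np.where(covariate_probe, rng.normal(0.0, 0.08, n_probes), 0.0)
    eta += age_load[:, None] * age_z[None, :]
    eta += smoke_load[:, None] * cov["smoker"][None, :]
    batch_load = rng.normal(0.0, 0.15, n_probes)
    eta += batch_load[:, None] * batch[None, :]
    eta += rng.normal(0.0, noise_sd, size=(n_probes, n))
    beta = expit(eta)
    beta += spike_delta[:, None] * (groups == "case")[None, :]
    beta = np.clip(beta, _EPS, 1 - _EPS)

    # --- total intensities (for detection-p / call-rate QC) -------------------
    intensity = rng.normal(5000.0, 800.0, size=(n_probes, n)).clip(100.0)
    failed = rng.random((n_probes, n)) < 0.001
    intensity[failed] = rng.normal(500.0, 100.0, size=int(failed.sum())).clip(50.0)

    # --- control-probe intensities -------------------------------------------
    ctl_ids = controls["probe_id"].to_numpy()
    base = np.array([_CONTROL_BASE[c] for c in controls["control_class"]])
    ctl = base[:, None] * np.exp(0.3 * batch[None, :])
    ctl = ctl * np.exp(rng.normal(0.0, 0.05, size=ctl.shape))
    ctl = np.clip(ctl + rng.normal(0.0, 20.0, size=ctl.shape), 1.0, None)

    # --- burden and frailty index --------------------------------------------
    if truth_probes:
        idx = np.array([pid_index[p] for p in truth_probes])
        wts = np.array([truth_probes[p] for p in truth_probes])
        burden = wts @ beta[idx]  # weighted sum over spiked probes
    else:
        burden = rng.normal(0.0, 1.0, n)
    bz = (burden - burden.mean()) / max(burden.std(), 1e-12)
    r = score_index_r
    noise = rng.normal(0.0, 1.0, n)
    yz = r * bz + np.sqrt(max(0.0, 1 - r * r)) * noise
    vacs = np.clip(np.rint(32.0 + 16.0 * yz), 0, 120).astype(int)

    samples = pd.DataFrame(
        {
            "group": groups,
            "idu_recency": cov["idu_recency"],
            "age": cov["age"],
            "smoker": cov["smoker"],
            "audit_c": cov["audit_c"],
            "adherence": cov["adherence"],
            "log10_vl": cov["log10_vl"],
            "wbc": cov["wbc"],
            "self_reported_sex": "male",
            "vacs_index": vacs,
            "cohort_id": cohort_id,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = SimTruth(
        spike_probes=truth_probes,
        spike_regions=truth_regions,
        cell_proportions=pd.DataFrame(w, index=samples.index, columns=list(CELL_TYPES)),
        batch=pd.Series(batch, index=samples.index, name="batch"),
        burden=pd.Series(burden, index=samples.index, name="burden"),
        score_index_r=score_index_r,
    )

    study_manifest = pd.concat([full_genomic, controls], ignore_index=True)
    return MethylationStudy(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        intensity=pd.DataFrame(intensity, index=probe_ids, columns=sample_ids),
        control_intensities=pd.DataFrame(ctl, index=ctl_ids, columns=sample_ids),
        manifest=study_manifest,
        samples=samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PowerEstimate:
    power: float
    mc_se: float
    n_reps: int
    alpha: float


def estimate_power(
    n_case: int,
    n_control: int,
    delta_beta: float,
    sd_beta: float,
    alpha: float,
    n_reps: int,
    seed: int,
) -> PowerEstimate:
    """Monte-Carlo power of a single-probe two-group linear-model test.

    Simulates ``n_reps`` probes with a case/control mean difference of
    ``delta_beta`` and within-group SD ``sd_beta`` (the within-group SD is a
    required argument: design-stage power claims are meaningless without
    it), tests each with the equal-variance two-sample t test (identical to
    the one-covariate linear model), and reports the rejection fraction at
    ``alpha`` with its Monte-Carlo standard error.
    """
    if sd_beta <= 0:
        raise ValueError("sd_beta must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    x = rng.normal(delta_beta, sd_beta, size=(n_reps, n_case))
    y = rng.normal(0.0, sd_beta, size=(n_reps, n_control))
    res = stats.ttest_ind(x, y, axis=1, equal_var=True)
    power = float(np.mean(res.pvalue < alpha))
    mc_se = float(np.sqrt(max(power * (1 - power), 1.0 / n_reps) / n_reps))
    return PowerEstimate(power=power, mc_se=mc_se, n_reps=n_reps, alpha=alpha)
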