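"""Synthetic multimodal studies with recorded ground truth.

Every analysis stage in this package is exercised on simulated studies
that emulate the structure of a two-group awake-rat head-injury
experiment: sham controls (n = 6) and head-impacted animals (n = 8),
each contributing

* a 200-volume TR = 1 s BOLD run whose region signals follow a modular
  factor model (within-module correlation c, attenuated in the impacted
  group's affected region groups),
* a pre-contrast scan plus consecutive post-contrast QUTE-CE scans in
  which a minority of impacted-animal regions leak contrast (linear
  apparent-CBV drift with slope beta),
* an 11-volume single-shell DWI series (one b0 + ten directions at
  b = 1000 s/mm^2) generated from region-group tensors with group shifts
  (impacted: basal ganglia MD down / FA up, thalamus MD down, cerebellum
  FA down), and
* open-field tracks and novel-object contact times with expected
  investigation ratio above chance in both groups.

All generators derive per-modality random substreams from one global
seed, so a study is internally consistent yet each modality is
independently re-runnable, and identical seed + config reproduce outputs
bit for bit.  Ground truth (true slopes, tensors, correlations) is always
returned alongside the data; analysis modules never see it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .core import LabelAtlas, VolumeSeries
from .dwi import BTable, DEFAULT_DIRECTIONS

__all__ = [
    "SimulationConfig",
    "StudyGroundTruth",
    "make_phantom_atlas",
    "simulate_bold_study",
    "simulate_qutece_study",
    "simulate_dwi_study",
    "simulate_behavior_tracks",
    "BoldStudy",
    "QuteceStudy",
    "DwiStudy",
    "BehaviorStudy",
]

REGION_GROUPS = ("thalamus", "hippocampus", "basal ganglia", "cerebellum", "cerebrum")
BLOOD_GROUP = "blood"

# substream keys so each modality draws from an independent generator
_STREAMS = {"atlas": 1, "bold": 2, "qutece": 3, "dwi": 4, "behavior": 5}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the emulated experiment: group sizes 6 sham / 8
    impacted, 200-volume TR = 1 s BOLD, five post-contrast scans over 30
    minutes, single-shell b = 1000 DWI, and the qualitative group effects
    (connectivity attenuation 0.5 in the affected region groups; 12 leak
    regions in 4 of 8 impacted subjects vs 2 regions in 2 shams at
    beta = 3e-5 /s; basal ganglia MD x0.90 FA x1.15, thalamus MD x0.92,
    cerebellum FA x0.90).
    """

    seed: int = 0
    n_sham: int = 6
    n_impacted: int = 8
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_regions: int = 20

    # BOLD
    tr_s: float = 1.0
    n_volumes: int = 200
    within_module_corr: float = 0.6
    corr_subject_sd: float = 0.15
    attenuation: float = 0.5
    affected_groups_bold: tuple[str, ...] = (
        "cerebrum",
        "hippocampus",
        "cerebellum",
        "thalamus",
    )
    bold_voxel_noise_sd: float = 0.3
    nuisance_gain: float = 0.5
    n_outlier_spikes: int = 3

    # QUTE-CE
    post_contrast_scan_times_s: tuple[float, ...] = (0.0, 450.0, 900.0, 1350.0, 1800.0)
    baseline_cbv: float = 0.03
    leak_beta_per_s: float = 3e-5
    n_leak_regions_impacted: int = 12
    n_leak_subjects_impacted: int = 4
    n_leak_regions_sham: int = 2
    n_leak_subjects_sham: int = 2
    qutece_noise_sd: float = 0.002  # in qCBV units per voxel
    blood_pre_intensity: float = 1000.0
    blood_contrast_step: float = 2000.0
    tissue_pre_intensity: float = 600.0

    # DWI
    b_value: float = 1000.0
    dwi_s0: float = 1000.0
    dwi_noise_sd: float = 20.0
    dwi_noise_model: str = "gaussian"  # or "rician"
    md_mm2_s: dict = field(
        default_factory=lambda: {
            "thalamus": 0.72e-3,
            "hippocampus": 0.75e-3,
            "basal ganglia": 0.70e-3,
            "cerebellum": 0.70e-3,
            "cerebrum": 0.80e-3,
            BLOOD_GROUP: 3.0e-3,
        }
    )
    fa_base: dict = field(
        default_factory=lambda: {
            "thalamus": 0.30,
            "hippocampus": 0.20,
            "basal ganglia": 0.25,
            "cerebellum": 0.25,
            "cerebrum": 0.15,
            BLOOD_GROUP: 0.05,
        }
    )
    md_shift_impacted: dict = field(
        default_factory=lambda: {"basal ganglia": 0.90, "thalamus": 0.92}
    )
    fa_shift_impacted: dict = field(
        default_factory=lambda: {"basal ganglia": 1.15, "cerebellum": 0.90}
    )

    # behavior
    arena_width_cm: float = 60.9
    arena_height_cm: float = 69.2
    track_duration_s: float = 1200.0
    track_rate_hz: float = 5.0
    track_step_cm: float = 2.0
    center_bias: float = 0.1
    expected_ir: float = 0.65
    ir_sd: float = 0.08
    mean_total_contact_s: float = 40.0

    def __post_init__(self) -> None:
        if self.n_sham < 1 or self.n_impacted < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if not 0 <= self.within_module_corr < 1:
            raise ValueError("within-module correlation must lie in [0, 1)")
        if self.leak_beta_per_s < 0:
            raise ValueError("leak slope must be >= 0")
        if not 0 < self.baseline_cbv < 1:
            raise ValueError("baseline CBV fraction must lie in (0, 1)")
        t_max = max(self.post_contrast_scan_times_s) if self.post_contrast_scan_times_s else 0
        if self.baseline_cbv + self.leak_beta_per_s * t_max >= 1:
            raise ValueError(
                "unphysical leak: CBV0 + beta * t_max reaches 1 within the session"
            )
        for name, sd in (
            ("bold_voxel_noise_sd", self.bold_voxel_noise_sd),
            ("qutece_noise_sd", self.qutece_noise_sd),
            ("dwi_noise_sd", self.dwi_noise_sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.track_duration_s <= 0 or self.mean_total_contact_s <= 0:
            raise ValueError("durations must be positive")
        if self.dwi_noise_model not in ("gaussian", "rician"):
            raise ValueError("dwi_noise_model must be 'gaussian' or 'rician'")

    def rng(self, modality: str) -> np.random.Generator:
        """Per-modality substream derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[modality],))
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def subjects(self) -> pd.DataFrame:
        ids = [f"sham{i+1:02d}" for i in range(self.n_sham)] + [
            f"hit{i+1:02d}" for i in range(self.n_impacted)
        ]
        groups = ["sham"] * self.n_sham + ["impacted"] * self.n_impacted
        return pd.DataFrame({"subject_id": ids, "group": groups})


@dataclass
class StudyGroundTruth:
    """Record of the latent quantities the analyses estimate.

    Frames are filled by whichever simulator produced them:

    * ``subjects``: subject_id, group
    * ``bold``: subject_id, label_id, module, c (true within-module
      correlation, in [0, 1))
    * ``qutece``: subject_id, label_id, cbv0, beta_per_s (beta >= 0)
    * ``dwi``: subject_id, label_id, region_group, md_true, fa_true,
      lambda1..3 (> 0)
    * ``behavior``: group-level expected investigation ratio
    """

    subjects: pd.DataFrame
    bold: pd.DataFrame | None = None
    qutece: pd.DataFrame | None = None
    dwi: pd.DataFrame | None = None
    behavior: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.qutece is not None and np.any(self.qutece["beta_per_s"] < 0):
            raise ValueError("true leak slopes must be >= 0")
        if self.qutece is not None and not np.all(
            (self.qutece["cbv0"] > 0) & (self.qutece["cbv0"] < 1)
        ):
            raise ValueError("baseline CBV fractions must lie in (0, 1)")
        if self.bold is not None and not np.all(
            (self.bold["c"] >= 0) & (self.bold["c"] < 1)
        ):
            raise ValueError("true correlations must lie in [0, 1)")
        if self.dwi is not None and not np.all(
            self.dwi[["lambda1", "lambda2", "lambda3"]].to_numpy() > 0
        ):
            raise ValueError("true tensor eigenvalues must be positive")


def make_phantom_atlas(config: SimulationConfig) -> LabelAtlas:
    """Deterministic blocky label atlas with the study's region groups.

    The grid is tiled into contiguous rectangular blocks; the first
    ``n_regions`` blocks become brain areas cycled through the five
    anatomical region groups, and one extra block is the designated
    blood-pool reference label (the largest label id).  Hemisphere is
    assigned by x-position.  The same seed and config always give the
    identical label map.
    """
    if config.n_regions < 4:
        raise ValueError("need at least 4 regions")
    shape = config.grid_shape
    n_labels = config.n_regions + 1  # + blood
    if n_labels + 1 > np.prod(shape):
        raise ValueError("grid too small for the requested regions")
    k = int(np.ceil(n_labels ** (1 / 3)))
    splits = [np.array_split(np.arange(s), k) for s in shape]
    if any(len(block) == 0 for axis in splits for block in axis):
        raise ValueError("grid too small for the requested regions")
    labels = np.zeros(shape, dtype=np.int64)
    block_id = 0
    rows = []
    for ix, xs in enumerate(splits[0]):
        for ys in splits[1]:
            for zs in splits[2]:
                if block_id >= n_labels:
                    break
                label = block_id + 1
                labels[np.ix_(xs, ys, zs)] = label
                if label <= config.n_regions:
                    group = REGION_GROUPS[block_id % len(REGION_GROUPS)]
                    hemi = "left" if ix < len(splits[0]) / 2 else "right"
                    rows.append(
                        {
                            "label_id": label,
                            "area_name": f"{group.replace(' ', '_')}_{label:03d}",
                            "hemisphere": hemi,
                            "region_group": group,
                        }
                    )
                else:
                    rows.append(
                        {
                            "label_id": label,
                            "area_name": "blood_pool",
                            "hemisphere": "midline",
                            "region_group": BLOOD_GROUP,
                        }
                    )
                block_id += 1
    return LabelAtlas(labels=labels, regions=pd.DataFrame(rows))


def blood_label_of(atlas: LabelAtlas) -> int:
    row = atlas.regions.loc[atlas.regions["region_group"] == BLOOD_GROUP]
    if row.empty:
        raise ValueError("atlas has no blood-pool label")
    return int(row["label_id"].iloc[0])


def _tissue_labels(atlas: LabelAtlas) -> pd.DataFrame:
    return atlas.regions.loc[atlas.regions["region_group"] != BLOOD_GROUP]


# ---------------------------------------------------------------------------
# BOLD


@dataclass
class BoldStudy:
    """Region-level BOLD signals per subject plus rendering to volumes."""

    config: SimulationConfig
    atlas: LabelAtlas
    subjects: pd.DataFrame
    signals: dict  # subject_id -> DataFrame (T x regions, columns label_id)
    nuisance: dict  # subject_id -> DataFrame (T x confound columns)
    clean_signals: dict  # subject_id -> DataFrame, pre-nuisance latents
    ground_truth: StudyGroundTruth
    _render_rngs: dict = field(default_factory=dict, repr=False)

    def render_volumes(self, subject_id: str) -> VolumeSeries:
        """Broadcast region signals to voxels with i.i.d. voxel noise."""
        rng = self._render_rngs[subject_id]
        cfg = self.config
        t = cfg.n_volumes
        data = rng.normal(
            0.0, cfg.bold_voxel_noise_sd, size=self.atlas.labels.shape + (t,)
        )
        sig = self.signals[subject_id]
        for label_id in sig.columns:
            mask = self.atlas.labels == label_id
            data[mask, :] += sig[label_id].to_numpy()[None, :]
        times = np.arange(t, dtype=float) * cfg.tr_s
        return VolumeSeries(data=data, times_s=times)


def simulate_bold_study(
    config: SimulationConfig, atlas: LabelAtlas | None = None
) -> BoldStudy:
    """Modular-covariance BOLD signals for every subject.

    Each region group is one module with a shared factor F_m(t); region
    signals are sqrt(c) F_m + sqrt(1 - c) eps with i.i.d. unit-normal
    factors and noise, so the within-module pairwise correlation is
    exactly c.  Per subject and module, c is drawn around the configured
    level (``corr_subject_sd`` models between-animal variability) and
    multiplied by ``attenuation`` for impacted subjects in the affected
    region groups.  Known nuisance structure (six motion regressors,
    motion-outlier spikes, WM/CSF signals, linear drift) is mixed in with
    recorded coefficients; the clean latents are kept for oracle tests.
    """
    atlas = atlas if atlas is not None else make_phantom_atlas(config)
    rng = config.rng("bold")
    subjects = config.subjects
    tissue = _tissue_labels(atlas)
    modules = {
        g: list(sub["label_id"]) for g, sub in tissue.groupby("region_group")
    }
    t = config.n_volumes
    time = np.arange(t) * config.tr_s

    signals: dict = {}
    nuisance: dict = {}
    clean: dict = {}
    truth_rows = []
    render_rngs = {}
    for _, subj in subjects.iterrows():
        sid, group = subj["subject_id"], subj["group"]
        sub_signals = {}
        for gname, label_ids in sorted(modules.items()):
            c_target = config.within_module_corr
            if group == "impacted" and gname in config.affected_groups_bold:
                c_target = c_target * config.attenuation
            factor = rng.standard_normal(t)
            for label_id in label_ids:
                # per-region loading: pairwise within-module r_ij = sqrt(c_i c_j)
                c = float(
                    np.clip(rng.normal(c_target, config.corr_subject_sd), 0.0, 0.95)
                )
                eps = rng.standard_normal(t)
                sub_signals[label_id] = np.sqrt(c) * factor + np.sqrt(1 - c) * eps
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "label_id": int(label_id),
                        "module": gname,
                        "c": c,
                    }
                )
        latent = pd.DataFrame(sub_signals)
        # nuisance structure with known mixing
        motion = np.cumsum(rng.normal(0, 0.05, size=(t, 6)), axis=0)
        motion -= motion.mean(axis=0)
        wm = rng.standard_normal(t)
        csf = rng.standard_normal(t)
        drift = np.linspace(-1, 1, t)
        outlier = np.zeros(t)
        spikes = rng.choice(t, size=config.n_outlier_spikes, replace=False)
        outlier[spikes] = 1.0
        nuis = pd.DataFrame(
            np.column_stack([motion, outlier, wm, csf]),
            columns=[f"motion{i+1}" for i in range(6)] + ["outlier", "wm", "csf"],
        )
        gain = config.nuisance_gain
        mixed = latent.copy()
        n_regions = latent.shape[1]
        coeffs = rng.normal(0, gain, size=(nuis.shape[1], n_regions))
        mixed += nuis.to_numpy() @ coeffs
        mixed += np.outer(drift, rng.normal(0, gain, size=n_regions))
        mixed.loc[spikes] += rng.normal(0, 5 * gain, size=(len(spikes), n_regions))
        signals[sid] = mixed
        nuisance[sid] = nuis
        clean[sid] = latent
        render_rngs[sid] = np.random.default_rng(rng.integers(2**31))

    truth = StudyGroundTruth(subjects=subjects, bold=pd.DataFrame(truth_rows))
    return BoldStudy(
        config=config,
        atlas=atlas,
        subjects=subjects,
        signals=signals,
        nuisance=nuisance,
        clean_signals=clean,
        ground_truth=truth,
        _render_rngs=render_rngs,
    )


# ---------------------------------------------------------------------------
# QUTE-CE


@dataclass
class QuteceStudy:
    """Pre-contrast and consecutive post-contrast volumes per subject."""

    config: SimulationConfig
    atlas: LabelAtlas
    subjects: pd.DataFrame
    pre: dict  # subject_id -> VolumeSeries (3D)
    post: dict  # subject_id -> list[VolumeSeries] per scan time
    scan_times_s: np.ndarray
    ground_truth: StudyGroundTruth

    @property
    def blood_label(self) -> int:
        return blood_label_of(self.atlas)


def simulate_qutece_study(
    config: SimulationConfig, atlas: LabelAtlas | None = None
) -> QuteceStudy:
    """Pre/post-contrast intensity volumes with configurable leak regions.

    The blood-pool label's post-contrast intensity is raised by a fixed
    contrast step.  Tissue voxels follow
    I'(t) = I + (CBV0 + beta t) (I'_B - I_B) + noise, with beta > 0 only in
    the configured leak regions of the configured subjects (defaults: 12
    regions in the first 4 impacted subjects, 2 regions in the first 2
    shams).  Voxel noise is Gaussian with SD ``qutece_noise_sd`` expressed
    in qCBV units (scaled by the blood intensity step).
    """
    atlas = atlas if atlas is not None else make_phantom_atlas(config)
    rng = config.rng("qutece")
    cfg = config
    times = np.asarray(cfg.post_contrast_scan_times_s, dtype=float)
    if times.size < 3:
        raise ValueError("need >= 3 post-contrast scan times")
    subjects = cfg.subjects
    tissue = _tissue_labels(atlas)
    tissue_ids = list(tissue["label_id"])
    blood = blood_label_of(atlas)

    if cfg.n_leak_regions_impacted > len(tissue_ids) or cfg.n_leak_regions_sham > len(
        tissue_ids
    ):
        raise ValueError("more leak regions requested than tissue regions exist")
    leak_regions_impacted = list(
        rng.choice(tissue_ids, size=cfg.n_leak_regions_impacted, replace=False)
    )
    leak_regions_sham = list(
        rng.choice(tissue_ids, size=cfg.n_leak_regions_sham, replace=False)
    )
    sham_ids = list(subjects.loc[subjects["group"] == "sham", "subject_id"])
    hit_ids = list(subjects.loc[subjects["group"] == "impacted", "subject_id"])
    leak_subjects = {
        **{s: leak_regions_sham for s in sham_ids[: cfg.n_leak_subjects_sham]},
        **{s: leak_regions_impacted for s in hit_ids[: cfg.n_leak_subjects_impacted]},
    }

    noise_sd_intensity = cfg.qutece_noise_sd * cfg.blood_contrast_step
    pre_vols: dict = {}
    post_vols: dict = {}
    truth_rows = []
    shape = atlas.labels.shape
    for _, subj in subjects.iterrows():
        sid = subj["subject_id"]
        leaks = set(leak_subjects.get(sid, []))
        pre = np.full(shape, cfg.tissue_pre_intensity)
        pre[atlas.labels == blood] = cfg.blood_pre_intensity
        pre[atlas.labels == 0] = 0.0
        pre_vols[sid] = VolumeSeries(data=pre.copy())
        posts = []
        betas = {
            int(lab): (cfg.leak_beta_per_s if lab in leaks else 0.0)
            for lab in tissue_ids
        }
        for t_k in times:
            vol = np.zeros(shape)
            vol[atlas.labels == blood] = (
                cfg.blood_pre_intensity + cfg.blood_contrast_step
            )
            for lab in tissue_ids:
                mask = atlas.labels == lab
                cbv_t = cfg.baseline_cbv + betas[int(lab)] * t_k
                vol[mask] = (
                    cfg.tissue_pre_intensity + cbv_t * cfg.blood_contrast_step
                )
                if noise_sd_intensity > 0:
                    vol[mask] += rng.normal(0, noise_sd_intensity, size=mask.sum())
            posts.append(VolumeSeries(data=vol))
        post_vols[sid] = posts
        for lab in tissue_ids:
            truth_rows.append(
                {
                    "subject_id": sid,
                    "label_id": int(lab),
                    "cbv0": cfg.baseline_cbv,
                    "beta_per_s": betas[int(lab)],
                }
            )
    truth = StudyGroundTruth(subjects=subjects, qutece=pd.DataFrame(truth_rows))
    return QuteceStudy(
        config=cfg,
        atlas=atlas,
        subjects=subjects,
        pre=pre_vols,
        post=post_vols,
        scan_times_s=times,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# DWI


def tensor_from_md_fa(md: float, fa: float) -> np.ndarray:
    """Axially symmetric tensor eigenvalues (descending) with given MD, FA.

    lambda1 = MD (1 + 2 rho), lambda2 = lambda3 = MD (1 - rho) with
    rho = FA / sqrt(3 - 2 FA^2); valid for 0 <= FA < 1.
    """
    if not 0 <= fa < 1:
        raise ValueError("FA must lie in [0, 1)")
    if md <= 0:
        raise ValueError("MD must be positive")
    rho = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return np.array([md * (1 + 2 * rho), md * (1 - rho), md * (1 - rho)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass
class DwiStudy:
    """Per-subject 11-volume DWI series with the shared b-table."""

    config: SimulationConfig
    atlas: LabelAtlas
    subjects: pd.DataFrame
    volumes: dict  # subject_id -> VolumeSeries (X, Y, Z, 11)
    btable: BTable
    ground_truth: StudyGroundTruth


def simulate_dwi_study(
    config: SimulationConfig, atlas: LabelAtlas | None = None
) -> DwiStudy:
    """Single-shell DWI from region-group tensors with group shifts.

    Per voxel, S(g) = S0 exp(-b g^T D g) plus Gaussian (default) or Rician
    noise.  D is the region's axially symmetric tensor, randomly rotated
    per region (rotation shared across subjects so group contrasts are
    purely MD/FA shifts); impacted subjects apply the configured
    multiplicative MD/FA shifts in the affected region groups, recorded
    exactly in the ground truth.
    """
    atlas = atlas if atlas is not None else make_phantom_atlas(config)
    rng = config.rng("dwi")
    cfg = config
    btable = BTable.single_shell(b=cfg.b_value, directions=DEFAULT_DIRECTIONS)
    subjects = cfg.subjects
    rotations = {
        int(row["label_id"]): _random_rotation(rng)
        for _, row in atlas.regions.iterrows()
    }
    g = btable.bvecs.T  # (N, 3)
    bv = btable.bvals

    volumes: dict = {}
    truth_rows = []
    shape = atlas.labels.shape
    for _, subj in subjects.iterrows():
        sid, group = subj["subject_id"], subj["group"]
        data = np.zeros(shape + (bv.size,))
        for _, row in atlas.regions.iterrows():
            lab = int(row["label_id"])
            rgroup = row["region_group"]
            md = cfg.md_mm2_s[rgroup]
            fa = cfg.fa_base[rgroup]
            if group == "impacted":
                md *= cfg.md_shift_impacted.get(rgroup, 1.0)
                fa *= cfg.fa_shift_impacted.get(rgroup, 1.0)
            eigs = tensor_from_md_fa(md, fa)
            rot = rotations[lab]
            d = rot @ np.diag(eigs) @ rot.T
            quad = np.einsum("ni,ij,nj->n", g, d, g)  # g^T D g per direction
            signal = cfg.dwi_s0 * np.exp(-bv * quad)
            mask = atlas.labels == lab
            data[mask, :] = signal[None, :]
            truth_rows.append(
                {
                    "subject_id": sid,
                    "label_id": lab,
                    "region_group": rgroup,
                    "md_true": md,
                    "fa_true": fa,
                    "lambda1": eigs[0],
                    "lambda2": eigs[1],
                    "lambda3": eigs[2],
                }
            )
        if cfg.dwi_noise_sd > 0:
            brain = atlas.labels > 0
            if cfg.dwi_noise_model == "gaussian":
                data[brain, :] += rng.normal(
                    0, cfg.dwi_noise_sd, size=(int(brain.sum()), bv.size)
                )
            else:  # rician: magnitude of complex Gaussian noise around signal
                re = data[brain, :] + rng.normal(
                    0, cfg.dwi_noise_sd, size=(int(brain.sum()), bv.size)
                )
                im = rng.normal(0, cfg.dwi_noise_sd, size=(int(brain.sum()), bv.size))
                data[brain, :] = np.sqrt(re**2 + im**2)
        times = np.arange(bv.size, dtype=float)
        volumes[sid] = VolumeSeries(data=data, times_s=times)
    truth = StudyGroundTruth(subjects=subjects, dwi=pd.DataFrame(truth_rows))
    return DwiStudy(
        config=cfg,
        atlas=atlas,
        subjects=subjects,
        volumes=volumes,
        btable=btable,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# behavior


@dataclass
class BehaviorStudy:
    config: SimulationConfig
    subjects: pd.DataFrame
    tracks: dict  # subject_id -> DataFrame (t, x, y)
    contacts: pd.DataFrame  # subject_id, group, novel_s, familiar_s
    ground_truth: StudyGroundTruth


def simulate_behavior_tracks(config: SimulationConfig) -> BehaviorStudy:
    """Reflected random-walk open-field tracks and NOR contact times.

    Tracks start at the arena centre and take Gaussian steps with a mild
    drift toward the centre (``center_bias``), reflected at the walls.
    NOR contact times are drawn so both groups share the configured
    expected investigation ratio (above chance, the null group-difference
    scenario): per subject, IR ~ Normal(expected_ir, ir_sd) clipped to
    (0.05, 0.95) and split over a random total contact time.
    """
    cfg = config
    if cfg.arena_width_cm <= 16 or cfg.arena_height_cm <= 16:
        raise ValueError("arena must exceed twice the 8 cm border")
    rng = cfg.rng("behavior")
    subjects = cfg.subjects
    n_samples = int(cfg.track_duration_s * cfg.track_rate_hz)
    dt = 1.0 / cfg.track_rate_hz
    tracks: dict = {}
    contact_rows = []
    for _, subj in subjects.iterrows():
        sid, group = subj["subject_id"], subj["group"]
        pos = np.empty((n_samples, 2))
        pos[0] = (cfg.arena_width_cm / 2, cfg.arena_height_cm / 2)
        center = np.array([cfg.arena_width_cm / 2, cfg.arena_height_cm / 2])
        step_sd = cfg.track_step_cm
        for i in range(1, n_samples):
            drift = cfg.center_bias * (center - pos[i - 1]) * dt
            step = rng.normal(0, step_sd, size=2) + drift
            nxt = pos[i - 1] + step
            # reflect at walls
            nxt[0] = np.clip(
                np.abs(nxt[0]) if nxt[0] < 0 else nxt[0], 0, None
            )
            if nxt[0] > cfg.arena_width_cm:
                nxt[0] = 2 * cfg.arena_width_cm - nxt[0]
            nxt[1] = np.abs(nxt[1])
            if nxt[1] > cfg.arena_height_cm:
                nxt[1] = 2 * cfg.arena_height_cm - nxt[1]
            nxt[0] = np.clip(nxt[0], 0, cfg.arena_width_cm)
            nxt[1] = np.clip(nxt[1], 0, cfg.arena_height_cm)
            pos[i] = nxt
        tracks[sid] = pd.DataFrame(
            {"t": np.arange(n_samples) * dt, "x": pos[:, 0], "y": pos[:, 1]}
        )
        ir = float(np.clip(rng.normal(cfg.expected_ir, cfg.ir_sd), 0.05, 0.95))
        total = max(float(rng.normal(cfg.mean_total_contact_s, 8.0)), 5.0)
        contact_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "novel_s": ir * total,
                "familiar_s": (1 - ir) * total,
            }
        )
    truth = StudyGroundTruth(
        subjects=subjects,
        behavior=pd.DataFrame(
            {
                "group": ["sham", "impacted"],
                "expected_ir": [cfg.expected_ir, cfg.expected_ir],
            }
        ),
    )
    return BehaviorStudy(
        config=cfg,
        subjects=subjects,
        tracks=tracks,
        contacts=pd.DataFrame(contact_rows),
        ground_truth=truth,
    )
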