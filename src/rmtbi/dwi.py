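"""Single-shell diffusion-tensor fitting, ADC/FA maps, and regional group tests.

The acquisition modelled here is one b = 0 volume plus ten non-collinear
diffusion-weighted volumes at b = 1000 s/mm^2.  Per voxel the tensor D is
estimated by ordinary least squares on the log-linearised Stejskal-Tanner
signal, ln S = ln S0 - b g^T D g, a deterministic seven-parameter fit.
Scalar maps follow from the eigenvalues: ADC is the mean diffusivity
(l1 + l2 + l3)/3 and FA the fractional anisotropy.  Regional statistics use
brain-area means as observations and compare groups nonparametrically
(Kruskal-Wallis gate, then an exact Wilcoxon rank-sum post hoc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import LabelAtlas, VolumeSeries

__all__ = [
    "DEFAULT_DIRECTIONS",
    "BTable",
    "TensorFit",
    "fit_tensor_loglinear",
    "scalar_maps",
    "aggregate_regional_scalars",
    "compare_regions_nonparametric",
]

#: Fixed electrostatic (antipodally symmetric minimum-energy) set of ten
#: unit gradient directions shipped with the package.
DEFAULT_DIRECTIONS = np.array(
    [
        (0.069273921298741, 0.062388444931498, 0.995644919520471),
        (0.762731205860653, -0.127304172332154, 0.634062106826437),
        (0.135754995207822, -0.651267637510022, 0.746606352509968),
        (-0.957987796532267, -0.286490470164606, 0.013512668134558),
        (0.465088759710562, 0.698810629719379, 0.543466787745209),
        (-0.349139938194841, 0.665368784368371, 0.659837619680372),
        (0.196907333163166, -0.979937420424916, 0.030824571327622),
        (-0.851007491395761, 0.523708939850159, 0.038925517457282),
        (-0.675400127255719, -0.060331008446534, 0.734979481021601),
        (-0.507316323190062, -0.805020126452517, 0.307526818718773),
    ]
)


@dataclass
class BTable:
    """Diffusion b-values (s/mm^2) and unit gradient directions (3 x N)."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (self.bvals.size, 3):
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (3, self.bvals.size):
            raise ValueError("bvecs must be 3 x N matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(self.bvecs, axis=0)
        weighted = self.bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit-norm (tol 1e-6)")

    @classmethod
    def single_shell(cls, b: float = 1000.0, directions: np.ndarray | None = None
                     ) -> "BTable":
        """One b0 plus a single shell over the default 10 directions."""
        if b <= 0:
            raise ValueError("shell b-value must be positive")
        dirs = DEFAULT_DIRECTIONS if directions is None else np.asarray(directions)
        bvals = np.concatenate([[0.0], np.full(len(dirs), b)])
        bvecs = np.vstack([np.zeros(3), dirs]).T
        return cls(bvals=bvals, bvecs=bvecs)

    def design_matrix(self) -> np.ndarray:
        """N x 7 log-linear design: [1, -b gx^2, -b gy^2, -b gz^2,
        -2b gx gy, -2b gx gz, -2b gy gz]."""
        g = self.bvecs
        b = self.bvals
        return np.column_stack(
            [
                np.ones_like(b),
                -b * g[0] ** 2,
                -b * g[1] ** 2,
                -b * g[2] ** 2,
                -2 * b * g[0] * g[1],
                -2 * b * g[0] * g[2],
                -2 * b * g[1] * g[2],
            ]
        )

    def save_fsl(self, prefix) -> None:
        """Write FSL-style .bval / .bvec text files."""
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(str(prefix) + ".bval", self.bvals[None, :], fmt="%.1f")
        np.savetxt(str(prefix) + ".bvec", self.bvecs, fmt="%.15f")

    @classmethod
    def load_fsl(cls, prefix) -> "BTable":
        bvals = np.loadtxt(str(prefix) + ".bval").ravel()
        bvecs = np.loadtxt(str(prefix) + ".bvec")
        return cls(bvals=bvals, bvecs=bvecs)


@dataclass
class TensorFit:
    """Voxelwise tensor estimates.

    ``tensor`` stores the six unique elements (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in mm^2/s, ``s0`` the non-diffusion-weighted signal estimate,
    ``eigenvalues`` the sorted (descending) tensor eigenvalues, and two QC
    masks: ``valid`` marks voxels that could be fit (all signals positive,
    full-rank design) and ``negative_eig`` flags voxels whose fitted tensor
    had a negative eigenvalue (clamped to 0 for FA).
    """

    tensor: np.ndarray
    s0: np.ndarray
    eigenvalues: np.ndarray
    valid: np.ndarray
    negative_eig: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.negative_eig is None:
            self.negative_eig = np.any(self.eigenvalues < 0, axis=-1)


def fit_tensor_loglinear(
    signals: np.ndarray, btable: BTable, volume_mask: np.ndarray | None = None
) -> TensorFit:
    """Ordinary least squares tensor fit on log signals.

    Parameters
    ----------
    signals : array (..., N) of measured signals, one per b-table entry.
        Any leading shape (single voxel, a voxel list, or a 3D grid).
    btable : acquisition table; needs >= 7 usable measurements including a
        b0 for an identifiable fit.
    volume_mask : optional boolean (N,) keep-mask for acquisitions, the
        motion-screening hook: volumes flagged False (e.g. by visual
        artifact screening) are excluded from every voxel's fit.

    Voxels with any non-positive retained signal are flagged invalid and
    excluded from downstream maps rather than aborting the whole fit.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != btable.bvals.size:
        raise ValueError("last signal axis must match the b-table length")
    keep = np.ones(btable.bvals.size, dtype=bool)
    if volume_mask is not None:
        keep = np.asarray(volume_mask, dtype=bool)
        if keep.shape != (btable.bvals.size,):
            raise ValueError("volume_mask must have one entry per acquisition")
    if keep.sum() < 7:
        raise ValueError("need >= 7 retained measurements to fit a tensor")
    if not np.any(btable.bvals[keep] == 0):
        raise ValueError("retained measurements must include a b0")

    design = btable.design_matrix()[keep]
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("rank-deficient diffusion design matrix")
    pinv = np.linalg.pinv(design)

    lead_shape = signals.shape[:-1]
    flat = signals.reshape(-1, signals.shape[-1])[:, keep]
    valid = np.all(flat > 0, axis=1)
    coeffs = np.zeros((flat.shape[0], 7))
    if valid.any():
        coeffs[valid] = np.log(flat[valid]) @ pinv.T

    s0 = np.exp(coeffs[:, 0])
    s0[~valid] = np.nan
    d6 = coeffs[:, 1:]
    mats = np.zeros((flat.shape[0], 3, 3))
    mats[:, 0, 0] = d6[:, 0]
    mats[:, 1, 1] = d6[:, 1]
    mats[:, 2, 2] = d6[:, 2]
    mats[:, 0, 1] = mats[:, 1, 0] = d6[:, 3]
    mats[:, 0, 2] = mats[:, 2, 0] = d6[:, 4]
    mats[:, 1, 2] = mats[:, 2, 1] = d6[:, 5]
    eigs = np.linalg.eigvalsh(mats)[:, ::-1]  # descending
    eigs[~valid] = np.nan

    return TensorFit(
        tensor=d6.reshape(lead_shape + (6,)),
        s0=s0.reshape(lead_shape),
        eigenvalues=eigs.reshape(lead_shape + (3,)),
        valid=valid.reshape(lead_shape),
        negative_eig=(np.any(eigs < 0, axis=-1) & valid).reshape(lead_shape),
    )


def scalar_maps(fit: TensorFit) -> tuple[np.ndarray, np.ndarray]:
    """ADC (mean diffusivity) and FA maps from a tensor fit.

    ADC = (l1 + l2 + l3) / 3.  FA uses eigenvalues clamped at 0 (negative
    values arise from noise and are flagged in ``fit.negative_eig``):

        FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2),

    defined as 0 for an all-zero tensor.  Invalid voxels are NaN.
    """
    eigs = fit.eigenvalues
    adc = eigs.mean(axis=-1)
    lam = np.clip(eigs, 0.0, None)
    lbar = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - lbar) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.where(np.isnan(adc), np.nan, fa)
    return adc, fa


def aggregate_regional_scalars(
    adc: np.ndarray,
    fa: np.ndarray,
    atlas: LabelAtlas,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Per-area mean ADC and FA for one subject.

    Output columns: subject_id, label_id, area_name, region_group,
    mean_adc, mean_fa, n_voxels.  Areas with no voxels (or only invalid
    voxels) are omitted with a warning.
    """
    adc = np.asarray(adc, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if adc.shape != atlas.labels.shape or fa.shape != atlas.labels.shape:
        raise ValueError("scalar maps and atlas must share the grid")
    rows = []
    for _, region in atlas.regions.iterrows():
        label_id = int(region["label_id"])
        mask = atlas.labels == label_id
        vals_adc = adc[mask]
        ok = np.isfinite(vals_adc)
        if not ok.any():
            warnings.warn(
                f"area {label_id} has no usable voxels and is omitted",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "label_id": label_id,
                "area_name": region["area_name"],
                "region_group": region["region_group"],
                "mean_adc": float(vals_adc[ok].mean()),
                "mean_fa": float(fa[mask][ok].mean()),
                "n_voxels": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def compare_regions_nonparametric(
    regional: pd.DataFrame,
    value: str = "mean_adc",
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis region screen with exact rank-sum post hoc.

    Observations are brain-area values: within each region group, every
    area's value is first averaged across the subjects of each experimental
    group, giving one dot per area per group (the granularity of regional
    dot plots).  A Kruskal-Wallis test across experimental groups gates at
    ``alpha``; where it passes, a two-sided exact Wilcoxon rank-sum
    (Mann-Whitney) post hoc and the direction of the effect are reported.

    Regions where any experimental group has fewer than 2 areas are
    skipped with a warning.
    """
    needed = {"label_id", "region_group", value, group_col}
    missing = needed - set(regional.columns)
    if missing:
        raise ValueError(f"regional table missing columns {sorted(missing)}")
    groups = sorted(regional[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 experimental groups")
    area_means = (
        regional.groupby([group_col, "region_group", "label_id"])[value]
        .mean()
        .reset_index()
    )
    rows = []
    for region, reg in area_means.groupby("region_group"):
        samples = [
            reg.loc[reg[group_col] == g, value].to_numpy() for g in groups
        ]
        if any(s.size < 2 for s in samples):
            warnings.warn(
                f"region group {region!r} has a group with < 2 areas; skipped",
                stacklevel=2,
            )
            continue
        if all(np.array_equal(s, samples[0]) for s in samples[1:]):
            h, p_kw = 0.0, 1.0  # identical groups: exact null
        else:
            h, p_kw = stats.kruskal(*samples)
        row = {
            "region_group": region,
            "n_areas": int(samples[0].size),
            "kw_H": float(h),
            "kw_p": float(p_kw),
            "flagged": bool(p_kw < alpha),
            "ranksum_W": np.nan,
            "ranksum_p": np.nan,
            "direction": "",
        }
        for g, s in zip(groups, samples):
            row[f"mean_{g}"] = float(s.mean())
        if p_kw < alpha and len(groups) == 2:
            res = stats.mannwhitneyu(
                samples[0], samples[1], alternative="two-sided", method="exact"
            )
            row["ranksum_W"] = float(res.statistic)
            row["ranksum_p"] = float(res.pvalue)
            row["direction"] = (
                f"{groups[0]} < {groups[1]}"
                if samples[0].mean() < samples[1].mean()
                else f"{groups[0]} > {groups[1]}"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dwi_study_scalars(
    dwi: VolumeSeries | np.ndarray, btable: BTable, atlas: LabelAtlas,
    subject_id: str = "subject", volume_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Convenience: fit tensors over a 4D DWI volume and aggregate regionally."""
    data = dwi.data if isinstance(dwi, VolumeSeries) else np.asarray(dwi, float)
    fit = fit_tensor_loglinear(data, btable, volume_mask=volume_mask)
    adc, fa = scalar_maps(fit)
    regional = aggregate_regional_scalars(adc, fa, atlas, subject_id=subject_id)
    return regional, adc, fa
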