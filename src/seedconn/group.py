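"""Group-level DMN inference and the between-strain strength comparison.

Subject seed-correlation maps are combined in Fisher-z space: the group
map is tanh(mean z), and the default-mode-network mask is the set of
voxels whose z values exceed atanh(r0) by a one-sample t-test (one-sided,
upper tail) at a Bonferroni-corrected level. The between-group strength
comparison pools each group's DMN voxels and applies a Welch two-sample
t-test on the group-mean z values.

The Bonferroni family size defaults to the group size (n subjects), the
convention that reproduces per-test levels of 0.0056 for n = 9 and 0.0062
for n = 8 at alpha = 0.05. This is unconventional — multiple-comparison
families are usually the number of tests — so the family size is an
explicit, reported parameter everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_DOWN, Decimal

import numpy as np
from scipy import stats

from .connectivity import SubjectCorrMap, fisher_z
from .core import ROIAtlas

__all__ = [
    "GroupDMNMap",
    "StrengthComparison",
    "group_mean_map",
    "bonferroni_alpha",
    "reported_threshold",
    "one_sample_threshold",
    "dmn_histogram",
    "compare_strength",
    "count_pixels",
    "welch_ttest",
    "SeedDMN",
    "SeedDMNResults",
]


def bonferroni_alpha(alpha: float, family_size: int) -> float:
    """Per-test level alpha / family_size (raw value, used internally)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")
    return alpha / family_size


def reported_threshold(alpha: float, family_size: int) -> float:
    """Per-test level rounded to 4 decimals for display (half toward zero).

    0.05/9 reports as 0.0056 and 0.05/8 (exactly 0.00625) as 0.0062.
    """
    raw = Decimal(str(alpha)) / Decimal(family_size)
    return float(raw.quantize(Decimal("0.0001"), rounding=ROUND_HALF_DOWN))


def _stack_maps(maps: list[SubjectCorrMap]) -> tuple[np.ndarray, np.ndarray]:
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    shape = maps[0].r_map.shape
    for m in maps:
        if m.r_map.shape != shape:
            raise ValueError("subject maps are on inconsistent grids")
    z = np.stack([m.z_map for m in maps])
    valid = np.stack([m.valid_mask for m in maps])
    return z, valid


def group_mean_map(maps: list[SubjectCorrMap]) -> tuple[np.ndarray, np.ndarray]:
    """Group mean correlation map via z-space averaging.

    Per voxel: mean of the subject z values over subjects where the voxel
    is valid, transformed back with tanh. Returns (mean_r_map, valid)
    where valid marks voxels defined in at least 2 subjects.
    """
    z, valid = _stack_maps(maps)
    n = valid.sum(axis=0)
    ok = n >= 2
    zsum = np.where(valid, z, 0.0).sum(axis=0)
    mean_r = np.zeros(z.shape[1:])
    mean_r[ok] = np.tanh(zsum[ok] / n[ok])
    return mean_r, ok


@dataclass
class GroupDMNMap:
    """Group DMN inference output: maps, mask, pixel count, thresholds."""

    mean_r_map: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    dmn_mask: np.ndarray
    valid: np.ndarray
    r0: float
    alpha: float
    family_size: int
    n_subjects: int
    space: str = "z"

    @property
    def pixel_count(self) -> int:
        return int(self.dmn_mask.sum())

    @property
    def per_test_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, self.family_size)

    @property
    def reported_alpha(self) -> float:
        return reported_threshold(self.alpha, self.family_size)

    def save(self, out_dir, prefix="group", voxel_dims=(0.469, 0.469, 1.0)) -> None:
        import nibabel as nib
        from pathlib import Path

        out_dir = Path(out_dir)
        affine = np.diag([*voxel_dims, 1.0])
        vols = {
            "mean_r": self.mean_r_map.astype(np.float32),
            "t": self.t_map.astype(np.float32),
            "p": self.p_map.astype(np.float32),
            "dmn_mask": self.dmn_mask.astype(np.uint8),
        }
        for suffix, vol in vols.items():
            nib.save(
                nib.Nifti1Image(vol, affine),
                str(out_dir / f"{prefix}_{suffix}.nii.gz"),
            )


def one_sample_threshold(
    maps: list[SubjectCorrMap],
    r0: float = 0.3,
    alpha: float = 0.05,
    family_size: int | None = None,
    space: str = "z",
) -> GroupDMNMap:
    """Voxelwise one-sample t-test against the null correlation r0.

    In the default z-space the test statistic at each voxel is
    t = (mean(z_i) - atanh(r0)) / (sd(z_i) / sqrt(n)) with df = n - 1,
    one-sided upper tail ("significantly larger than r0"); ``space='r'``
    runs the same test on the raw correlations against r0. A voxel enters
    the DMN mask iff p < alpha/family_size and its group mean r exceeds
    r0. Voxels with zero spread get p = 0 (mean above null) or 1.
    """
    if space not in ("z", "r"):
        raise ValueError("space must be 'z' or 'r'")
    z, valid = _stack_maps(maps)
    if space == "r":
        z = np.stack([m.r_map for m in maps])
        null = r0
    else:
        null = fisher_z(r0)
    n_sub = len(maps)
    family = n_sub if family_size is None else family_size
    per_test = bonferroni_alpha(alpha, family)

    n = valid.sum(axis=0)
    ok = n >= 2
    if not ok.any():
        raise ValueError("no voxel is valid in at least 2 subjects")

    vals = np.where(valid, z, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, vals.sum(axis=0) / np.maximum(n, 1), 0.0)
        ss = np.where(valid, (z - mean) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        se = sd / np.sqrt(np.maximum(n, 1))
        t = np.zeros_like(mean)
        p = np.ones_like(mean)
        nonzero = ok & (sd > 0)
        t[nonzero] = (mean[nonzero] - null) / se[nonzero]
        # upper-tail p with per-voxel df = n - 1
        p[nonzero] = stats.t.sf(t[nonzero], df=n[nonzero] - 1)
    degenerate = ok & (sd == 0)
    p[degenerate] = np.where(mean[degenerate] > null, 0.0, 1.0)
    t[degenerate & (mean > null)] = np.inf

    mean_r, _ = group_mean_map(maps)
    dmn = ok & (p < per_test) & (mean_r > r0)
    p[~ok] = 1.0
    return GroupDMNMap(
        mean_r_map=mean_r,
        t_map=t,
        p_map=p,
        dmn_mask=dmn,
        valid=ok,
        r0=r0,
        alpha=alpha,
        family_size=family,
        n_subjects=n_sub,
        space=space,
    )


def dmn_histogram(
    mean_r_map: np.ndarray, dmn_mask: np.ndarray, bins=None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of group-mean correlations inside the DMN mask."""
    dmn_mask = np.asarray(dmn_mask, dtype=bool)
    if not dmn_mask.any():
        raise ValueError("DMN mask is empty; no histogram to compute")
    if bins is None:
        bins = np.linspace(-1, 1, 41)
    counts, edges = np.histogram(mean_r_map[dmn_mask], bins=bins)
    return counts, edges


def count_pixels(dmn_mask: np.ndarray) -> int:
    """Number of voxels in the DMN mask."""
    return int(np.asarray(dmn_mask, dtype=bool).sum())


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns (t, p, df) with the Welch–Satterthwaite degrees of freedom.
    Implemented from the closed form so it vectorises over edges; the test
    suite cross-checks it against scipy's reference implementation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, 1.0, float(na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(min(p, 1.0)), float(df)


def student_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return 0.0, 1.0, float(df)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), float(min(2.0 * stats.t.sf(abs(t), df=df), 1.0)), float(df)


@dataclass
class StrengthComparison:
    """Between-group DMN connectivity-strength comparison."""

    mean_z_a: float
    mean_z_b: float
    sd_z_a: float
    sd_z_b: float
    t_stat: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    group_a: str = "A"
    group_b: str = "B"

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "group_a", "group_b", "mean_z_a", "mean_z_b", "sd_z_a", "sd_z_b",
                "t_stat", "p_value", "df", "n_a", "n_b",
            )
        }


def compare_strength(
    maps_a: list[SubjectCorrMap],
    maps_b: list[SubjectCorrMap],
    dmn_a: np.ndarray,
    dmn_b: np.ndarray,
    exclude_roi: str | None = None,
    atlas: ROIAtlas | None = None,
    equal_var: bool = False,
    group_a: str = "A",
    group_b: str = "B",
) -> StrengthComparison:
    """Welch two-sample t-test on pooled DMN voxel strengths.

    Sample A is the group-mean z value at every voxel of group A's DMN
    mask (likewise B). ``exclude_roi`` removes an ROI's voxels from both
    masks first (e.g. to test whether a difference survives without the
    caudate putamen). Voxels are treated as independent observations, as
    in voxel-pooled comparisons; this ignores spatial autocorrelation.
    """
    dmn_a = np.asarray(dmn_a, dtype=bool).copy()
    dmn_b = np.asarray(dmn_b, dtype=bool).copy()
    if exclude_roi is not None:
        if atlas is None:
            raise ValueError("exclude_roi requires an atlas")
        roi = atlas.roi_mask(exclude_roi)
        dmn_a &= ~roi
        dmn_b &= ~roi
    if not dmn_a.any() or not dmn_b.any():
        raise ValueError("a DMN mask is empty (possibly after ROI exclusion)")

    za, _ = _stack_maps(maps_a)
    zb, _ = _stack_maps(maps_b)
    sample_a = za.mean(axis=0)[dmn_a]
    sample_b = zb.mean(axis=0)[dmn_b]
    test = student_ttest if equal_var else welch_ttest
    t, p, df = test(sample_a, sample_b)
    return StrengthComparison(
        mean_z_a=float(sample_a.mean()),
        mean_z_b=float(sample_b.mean()),
        sd_z_a=float(sample_a.std(ddof=1)) if sample_a.size > 1 else 0.0,
        sd_z_b=float(sample_b.std(ddof=1)) if sample_b.size > 1 else 0.0,
        t_stat=t,
        p_value=p,
        df=df,
        n_a=int(sample_a.size),
        n_b=int(sample_b.size),
        group_a=group_a,
        group_b=group_b,
    )


class SeedDMN:
    """Group DMN model over per-subject seed-correlation maps.

    Statsmodels-style front end: construct from subject maps (or from raw
    images via :meth:`from_images`), call :meth:`fit` to obtain a
    :class:`SeedDMNResults` carrying the group maps, the thresholded DMN
    mask and the thresholds actually applied.
    """

    def __init__(
        self,
        maps: list[SubjectCorrMap],
        r0: float = 0.3,
        alpha: float = 0.05,
        family_size: int | None = None,
        space: str = "z",
    ):
        if len(maps) < 2:
            raise ValueError("need at least 2 subject maps")
        self.maps = list(maps)
        self.r0 = r0
        self.alpha = alpha
        self.family_size = family_size
        self.space = space

    @classmethod
    def from_images(
        cls,
        images,
        atlas: ROIAtlas,
        seed_roi: str = "RSC",
        preproc=None,
        subject_ids=None,
        **kwargs,
    ) -> "SeedDMN":
        """Preprocess raw images and build their seed-correlation maps."""
        from .connectivity import corr_map, roi_timecourse
        from .preprocess import preprocess_subject

        maps = []
        for i, img in enumerate(images):
            proc, mask = preprocess_subject(img, preproc)
            seed_ts = roi_timecourse(proc, atlas, seed_roi, mask)
            sid = subject_ids[i] if subject_ids else f"sub{i:02d}"
            maps.append(corr_map(proc, seed_ts, mask, seed_roi, sid))
        return cls(maps, **kwargs)

    def fit(self) -> "SeedDMNResults":
        dmn = one_sample_threshold(
            self.maps, self.r0, self.alpha, self.family_size, self.space
        )
        return SeedDMNResults(self, dmn)


class SeedDMNResults:
    """Fitted group DMN: maps, mask, counts, histogram and summary."""

    def __init__(self, model: SeedDMN, dmn: GroupDMNMap):
        self.model = model
        self.group_map = dmn

    @property
    def mean_r_map(self):
        return self.group_map.mean_r_map

    @property
    def dmn_mask(self):
        return self.group_map.dmn_mask

    @property
    def pixel_count(self) -> int:
        return self.group_map.pixel_count

    def histogram(self, bins=None):
        return dmn_histogram(self.mean_r_map, self.dmn_mask, bins)

    def plot_histogram(self, bins=None, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        counts, edges = self.histogram(bins)
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", **kwargs)
        ax.set_xlabel("group mean correlation r")
        ax.set_ylabel("voxel count")
        return ax

    def summary(self) -> str:
        g = self.group_map
        lines = [
            "Seed-based group DMN (one-sample t in "
            f"{'Fisher-z' if g.space == 'z' else 'r'} space)",
            "=" * 58,
            f"subjects:             {g.n_subjects}",
            f"null correlation r0:  {g.r0}",
            f"alpha (family-wise):  {g.alpha}",
            f"Bonferroni family:    {g.family_size}",
            f"per-test level:       {g.per_test_alpha:.6g} (reported {g.reported_alpha:.4f})",
            f"test:                 one-sided upper tail, df = n - 1",
            f"DMN pixel count:      {g.pixel_count}",
        ]
        if g.pixel_count:
            r = g.mean_r_map[g.dmn_mask]
            lines.append(
                f"DMN mean r (range):   {r.mean():.4f} ({r.min():.4f} .. {r.max():.4f})"
            )
        return "\n".join(lines)

    def save(self, out_dir, prefix="group", voxel_dims=(0.469, 0.469, 1.0)):
        self.group_map.save(out_dir, prefix, voxel_dims)
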