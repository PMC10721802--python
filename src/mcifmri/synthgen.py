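"""Synthetic rs-fMRI cohorts with known ground truth.

Real scanner data for the MCI-vs-control problem are access-controlled, so
this module generates stand-in cohorts at two levels:

* :func:`generate_image_cohort` — 4D BOLD-like volumes on a small grid with a
  deterministic box-tiling atlas. Every region carries a latent band-limited
  signal (sum of sinusoids inside 0.008–0.09 Hz) shared by its voxels, plus
  voxelwise white noise. Group effects for MCI subjects are planted in a
  known subset of regions through two independent channels: a low-frequency
  amplitude shift (moves fALFF and ICC) and a signal/noise mixing shift
  (moves within-region coherence, i.e. LCOR).
* :func:`generate_feature_table` — the same study design planted directly at
  the ROI-feature level: uninformative columns are standard normal, planted
  columns are mean-shifted by the configured Cohen's d in the MCI group.

All randomness flows from one integer seed; per-subject substreams are
derived from fixed offsets, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellate import METRICS, FeatureTable, Parcellation, feature_name
from .voxmetrics import BoldSeries

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "box_atlas",
    "generate_image_cohort",
    "generate_feature_table",
    "write_cohort_nifti",
]

# between-subject SD of the latent amplitude / noise-scale factors; the
# planted group shift is expressed in units of this SD so that downstream
# standardized differences track the configured effect size
SUBJECT_SD = 0.15
N_SINUSOIDS = 6
# channel gains calibrated so the mean standardized difference across the
# three downstream ROI metrics matches effect_size (the amplitude channel
# also leaks into fALFF through the noise share, hence the < 1 gain)
AMPLITUDE_GAIN = 0.6
COHERENCE_GAIN = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the local study arm (46 HC / 32 MCI, TR = 2 s, 300
    volumes, 132 regions); ``n_hc=86, n_mci=69`` gives the consortium-style
    arm. ``effect_size`` is the standardized mean difference (Cohen's d)
    planted on informative features; 0 yields exchangeable groups.
    """

    n_hc: int = 46
    n_mci: int = 32
    n_regions: int = 132
    volumes: int = 300
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] | None = None  # None: 2x2x2 voxels/region
    voxel_size_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    informative_regions: tuple[int, ...] = ()
    effect_size: float = 0.0
    amplitude_effect_size: float | None = None  # None: use effect_size
    coherence_effect_size: float | None = None  # None: use effect_size
    noise_sd: float = 1.0
    band_hz: tuple[float, float] = (0.008, 0.09)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_mci < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        bad = [r for r in self.informative_regions if not 1 <= r <= self.n_regions]
        if bad:
            raise ValueError(f"informative regions {bad} outside 1..{self.n_regions}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_mci

    @property
    def amplitude_effect(self) -> float:
        v = self.amplitude_effect_size
        return self.effect_size if v is None else v

    @property
    def coherence_effect(self) -> float:
        v = self.coherence_effect_size
        return self.effect_size if v is None else v


@dataclass
class SyntheticCohort:
    """Image-level cohort: subjects, atlas, and the planted ground truth."""

    subjects: list[tuple[str, str, BoldSeries]]  # (subject_id, group, series)
    atlas: Parcellation
    truth_mask: np.ndarray  # bool over the 3R concatenated feature columns
    truth_feature_names: list[str]
    config: CohortConfig

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            {sid: (0 if group == "HC" else 1) for sid, group, _ in self.subjects}
        )


def _near_cubic_factors(n: int) -> tuple[int, int, int]:
    """Deterministic factorization of n into three factors, as cubic as possible."""
    best = None
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(m ** 0.5) + 1):
            if m % b:
                continue
            c = m // b
            key = (c / a, a, b)  # minimize spread, then deterministic tie-break
            if best is None or key < best[0]:
                best = (key, (a, b, c))
    assert best is not None
    a, b, c = best[1]
    return a, b, c


def box_atlas(n_regions: int, grid_shape: tuple[int, int, int]) -> Parcellation:
    """Deterministic rectangular tiling of the grid into ``n_regions`` boxes."""
    na, nb, nc = _near_cubic_factors(n_regions)
    if grid_shape[0] < na or grid_shape[1] < nb or grid_shape[2] < nc:
        raise ValueError(
            f"grid {grid_shape} too small to tile into {na}x{nb}x{nc} boxes"
        )
    labels = np.zeros(grid_shape, dtype=np.int32)
    xs = np.array_split(np.arange(grid_shape[0]), na)
    ys = np.array_split(np.arange(grid_shape[1]), nb)
    zs = np.array_split(np.arange(grid_shape[2]), nc)
    region = 1
    for bx in xs:
        for by in ys:
            for bz in zs:
                labels[np.ix_(bx, by, bz)] = region
                region += 1
    return Parcellation(labels=labels)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,)))


def _subject_ids_groups(config: CohortConfig) -> list[tuple[str, str]]:
    out = []
    for i in range(config.n_subjects):
        group = "HC" if i < config.n_hc else "MCI"
        out.append((f"sub-{i + 1:04d}", group))
    return out


def generate_image_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate 4D volumes with planted group effects in known regions.

    Voxel model: ``x_v(t) = A_{s,r} * s_r(t) + B_{s,r} * noise_sd * eps_v(t)``
    where ``s_r`` is a unit-variance sum of in-band sinusoids with
    subject-specific phases, ``A`` and ``B`` vary between subjects with SD
    ``SUBJECT_SD``, and MCI subjects get ``A`` raised (amplitude channel) and
    ``B`` lowered (coherence channel) by ``gain * effect * SUBJECT_SD`` in the
    informative regions, with channel gains calibrated so the mean downstream
    standardized ROI difference tracks ``effect_size``.
    """
    grid = config.grid_shape
    if grid is None:
        na, nb, nc = _near_cubic_factors(config.n_regions)
        grid = (2 * na, 2 * nb, 2 * nc)
    atlas = box_atlas(config.n_regions, grid)
    counts = np.bincount(atlas.labels.ravel(), minlength=config.n_regions + 1)[1:]
    small = np.nonzero(counts < 8)[0] + 1
    if small.size:
        raise ValueError(
            f"region(s) {list(small)} have fewer than 8 voxels; enlarge grid_shape"
        )

    # region frequency sets are cohort-level (drawn once from the master seed)
    master = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0xC0,)))
    lo, hi = config.band_hz
    region_freqs = master.uniform(lo, hi, size=(config.n_regions, N_SINUSOIDS))

    t = np.arange(config.volumes) * config.tr_seconds
    informative = set(config.informative_regions)
    subjects: list[tuple[str, str, BoldSeries]] = []
    region_voxels = [np.argwhere(atlas.labels == r + 1) for r in range(config.n_regions)]

    for i, (sid, group) in enumerate(_subject_ids_groups(config)):
        rng = _subject_rng(config.seed, i)
        data = np.empty(grid + (config.volumes,))
        phases = rng.uniform(0, 2 * np.pi, size=(config.n_regions, N_SINUSOIDS))
        amp_factor = 1.0 + SUBJECT_SD * rng.standard_normal(config.n_regions)
        noise_factor = 1.0 + SUBJECT_SD * rng.standard_normal(config.n_regions)
        if group == "MCI" and informative:
            idx = np.array(sorted(informative)) - 1
            amp_factor[idx] += AMPLITUDE_GAIN * config.amplitude_effect * SUBJECT_SD
            noise_factor[idx] -= COHERENCE_GAIN * config.coherence_effect * SUBJECT_SD
        amp_factor = np.clip(amp_factor, 0.05, None)
        noise_factor = np.clip(noise_factor, 0.05, None)
        for r in range(config.n_regions):
            latent = np.sin(np.outer(region_freqs[r], t) * 2 * np.pi + phases[r][:, None]).sum(axis=0)
            latent = latent / max(latent.std(), 1e-12)
            vox = region_voxels[r]
            noise = rng.standard_normal((vox.shape[0], config.volumes))
            sig = amp_factor[r] * latent[None, :] + noise_factor[r] * config.noise_sd * noise
            data[vox[:, 0], vox[:, 1], vox[:, 2], :] = sig
        subjects.append(
            (
                sid,
                group,
                BoldSeries(
                    data=data,
                    voxel_size_mm=config.voxel_size_mm,
                    tr_seconds=config.tr_seconds,
                ),
            )
        )

    names, mask = _truth_columns(config, atlas.region_names)
    return SyntheticCohort(
        subjects=subjects,
        atlas=atlas,
        truth_mask=mask,
        truth_feature_names=names,
        config=config,
    )


def _truth_columns(config: CohortConfig, region_names: list[str]) -> tuple[list[str], np.ndarray]:
    names = [
        feature_name(metric, r + 1, region_names[r])
        for metric in METRICS
        for r in range(config.n_regions)
    ]
    informative = set(config.informative_regions)
    mask = np.array(
        [
            (r + 1) in informative
            for _metric in METRICS
            for r in range(config.n_regions)
        ],
        dtype=bool,
    )
    return names, mask


def generate_feature_table(config: CohortConfig) -> tuple[FeatureTable, np.ndarray]:
    """Plant the study design directly at the ROI-feature level.

    Returns the (n_hc + n_mci) x (3 * n_regions) table and the boolean truth
    mask over columns. Uninformative columns are N(0, 1) in both groups;
    planted columns are shifted by ``effect_size`` (in SD units, i.e. exact
    Cohen's d in expectation) for MCI subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0xF0,)))
    region_names = [f"region_{i:03d}" for i in range(1, config.n_regions + 1)]
    names, mask = _truth_columns(config, region_names)
    n, p = config.n_subjects, 3 * config.n_regions
    x = rng.standard_normal((n, p))
    ids_groups = _subject_ids_groups(config)
    y = np.array([0 if g == "HC" else 1 for _, g in ids_groups])
    x[np.ix_(y == 1, np.nonzero(mask)[0])] += config.effect_size
    frame = pd.DataFrame(x, index=[sid for sid, _ in ids_groups], columns=names)
    labels = pd.Series(y, index=frame.index)
    return FeatureTable(data=frame, labels=labels), mask


def write_cohort_nifti(cohort: SyntheticCohort, outdir) -> None:
    """Write per-subject 4D .nii.gz, the atlas, labels CSV and truth CSV."""
    import pathlib

    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = cohort.config.voxel_size_mm
    affine = np.diag(list(vs) + [1.0])
    for sid, _group, series in cohort.subjects:
        img = nib.Nifti1Image(series.data.astype(np.float32), affine)
        img.header.set_zooms(tuple(vs) + (cohort.config.tr_seconds,))
        nib.save(img, str(outdir / f"{sid}_bold.nii.gz"))
    nib.save(nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), affine), str(outdir / "atlas.nii.gz"))
    pd.DataFrame(
        [(sid, group) for sid, group, _ in cohort.subjects],
        columns=["subject_id", "group"],
    ).to_csv(outdir / "labels.csv", index=False)
    pd.DataFrame(
        {"feature": cohort.truth_feature_names, "informative": cohort.truth_mask.astype(int)}
    ).to_csv(outdir / "truth_mask.csv", index=False)
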