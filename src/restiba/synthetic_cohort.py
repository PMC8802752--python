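"""Seeded synthetic two-group resting-state BOLD cohorts with planted effects.

The generator emulates the ingredients the downstream pipeline must handle:
low-frequency (0.01-0.08 Hz) oscillatory signal embedded in white noise, two
groups (reverter-like vs control), multi-site acquisition with additive
intensity offsets and noise-scale multipliers, rigid-body motion traces, and
behavioural scores tied to the planted effect magnitude.

Signal model
------------
Each cohort draws one in-band sinusoid count (3-8, a paradigm-level
property); every voxel of every subject then receives that many sinusoids
with independent random frequencies in the band and independent random
phases, per-sinusoid amplitude ``signal_amp / sqrt(n_sin)`` so total signal
power does not depend on the drawn count.  Independent per-voxel frequency
draws keep background voxel pairs nearly uncorrelated, which is what lets
the synchrony/hub effects below stand out in ReHo and DC.  Planted effects
modulate this field inside spherical regions:

* ``amplitude`` — the sinusoid amplitude is multiplied by ``group_ratio`` in
  the reverter-like group (ALFF/fALFF/PerAF target);
* ``synchrony`` — all region voxels share one latent phase set, i.e. one
  latent time course (ReHo target), amplitude again scaled by ``group_ratio``
  in the reverter-like group;
* ``hub`` — region voxels and a random set of distant partner voxels share an
  additive latent course (DC target), with ``group_ratio`` scaling the latent
  amplitude in the reverter-like group.

All randomness flows from the root seed through named substreams, so a
(spec, seed) pair reproduces every file bit for bit.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, MotionTrace, default_affine

__all__ = [
    "SiteSpec",
    "EffectRegion",
    "CohortSpec",
    "SubjectSim",
    "sphere_mask",
    "tissue_masks",
    "generate_bold_subject",
    "generate_motion_trace",
    "generate_cohort",
    "planted_magnitudes",
    "generate_behavioral_scores",
    "behavioral_score_table",
    "write_cohort",
    "save_nifti_deterministic",
]

GROUPS = ("reverter", "control")
_STREAM_COHORT, _STREAM_BOLD, _STREAM_MOTION, _STREAM_SCORES = 0, 1, 2, 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass
class SiteSpec:
    """Acquisition site with an additive offset and a noise-scale multiplier."""

    name: str
    offset: float = 0.0
    noise_scale: float = 1.0
    groups: tuple[str, ...] = GROUPS


@dataclass
class EffectRegion:
    """Spherical planted effect; ``group_ratio`` applies to the reverter-like group."""

    center: tuple[int, int, int]
    radius: int
    kind: str  # amplitude | synchrony | hub
    group_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("amplitude", "synchrony", "hub"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.radius < 1:
            raise ValueError("effect radius must be >= 1 voxel")
        if self.group_ratio <= 0:
            raise ValueError("group_ratio must be positive")


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Presets for the acquisition protocols are TR 3.0 s / 197 volumes (basic)
    and TR 0.607 s / 976 volumes (multiband); the default is a desk-scale
    24^3 grid with 120 volumes at TR 3 s.
    """

    n_per_group: int = 12
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    tr_s: float = 3.0
    n_volumes: int = 120
    sites: list[SiteSpec] = field(default_factory=lambda: [
        SiteSpec("siteA"), SiteSpec("siteB", offset=20.0, noise_scale=1.2)])
    effects: list[EffectRegion] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_mean: float = 100.0
    signal_amp: float = 1.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    n_sinusoids_range: tuple[int, int] = (3, 8)
    hub_partner_fraction: float = 0.15
    hub_partner_weight: float = 0.7
    motion_severity: float = 0.02
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes <= 10:
            raise ValueError("need more than 10 volumes (initial-volume discard)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        nyquist = 1.0 / (2.0 * self.tr_s)
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band edge {self.band_high_hz} Hz >= Nyquist {nyquist:.4f} Hz "
                f"for TR {self.tr_s}s")
        for eff in self.effects:
            c = np.asarray(eff.center)
            if ((c - eff.radius < 0).any()
                    or (c + eff.radius >= np.asarray(self.grid_shape)).any()):
                raise ValueError(f"effect region {eff} extends outside the grid")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)


@dataclass
class SubjectSim:
    subject_id: str
    group: str
    site: str
    bold: BoldSeries
    motion: MotionTrace
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    effect_multipliers: list[float]
    age: float = 70.0
    sex: str = "F"
    education: float = 16.0


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def sphere_mask(grid_shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def tissue_masks(grid_shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic brain / WM / CSF masks for a grid.

    Brain is the interior box (one-voxel background rim); WM and CSF are small
    spheres in one octant.  The analysis mask used downstream is brain minus
    the two tissue compartments.
    """
    shape = tuple(grid_shape)
    brain = np.zeros(shape, dtype=bool)
    brain[tuple(slice(1, s - 1) for s in shape)] = True
    q = [max(2, s // 5) for s in shape]
    r = max(1, min(shape) // 10)
    wm = sphere_mask(shape, q, r) & brain
    csf = sphere_mask(shape, [s - 1 - qq for s, qq in zip(shape, q)], r) & brain
    return brain, wm, csf


def analysis_mask(grid_shape) -> np.ndarray:
    brain, wm, csf = tissue_masks(grid_shape)
    return brain & ~wm & ~csf


# ---------------------------------------------------------------------------
# Cohort-level draws
# ---------------------------------------------------------------------------

def _cohort_draws(spec: CohortSpec):
    """Sinusoid count and hub-partner voxels — shared across the cohort."""
    rng = _rng(spec.seed, _STREAM_COHORT)
    lo, hi = spec.n_sinusoids_range
    n_sin = int(rng.integers(lo, hi + 1))
    brain, _, _ = tissue_masks(spec.grid_shape)
    partners = {}
    for i, eff in enumerate(spec.effects):
        if eff.kind == "hub":
            region = sphere_mask(spec.grid_shape, eff.center, eff.radius)
            candidates = np.flatnonzero(brain & ~region)
            n_pick = int(round(spec.hub_partner_fraction * candidates.size))
            partners[i] = rng.choice(candidates, size=n_pick, replace=False)
    return n_sin, partners


# ---------------------------------------------------------------------------
# Per-subject generation
# ---------------------------------------------------------------------------

def hub_partner_mask(spec: CohortSpec, effect_index: int) -> np.ndarray:
    """Boolean mask of the distant voxels wired to a hub effect's latent course."""
    if spec.effects[effect_index].kind != "hub":
        raise ValueError("effect is not a hub")
    _, partners = _cohort_draws(spec)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask.ravel()[partners[effect_index]] = True
    return mask


def generate_bold_subject(spec: CohortSpec, group: str, site: str,
                          subject_index: int) -> BoldSeries:
    """One subject's 4D BOLD volume; deterministic per (spec, subject_index)."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    site_spec = next((s for s in spec.sites if s.name == site), None)
    if site_spec is None:
        raise ValueError(f"unknown site {site!r}")
    n_sin, partners = _cohort_draws(spec)
    rng = _rng(spec.seed, _STREAM_BOLD, subject_index)
    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    n_t = spec.n_volumes
    amp = spec.signal_amp / np.sqrt(n_sin)

    t = np.arange(n_t) * spec.tr_s

    def _course(freqs_s, phases_s):
        # sum of sinusoids for one latent time course
        return amp * np.sin(2.0 * np.pi * freqs_s[:, None] * t[None, :]
                            + phases_s[:, None]).sum(axis=0)

    freqs = rng.uniform(spec.band_low_hz, spec.band_high_hz, size=(n_vox, n_sin))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_vox, n_sin))
    mult = np.ones(n_vox)
    latent_add = np.zeros((n_vox, n_t))
    for i, eff in enumerate(spec.effects):
        region = sphere_mask(shape, eff.center, eff.radius).ravel()
        ratio = eff.group_ratio if group == "reverter" else 1.0
        if eff.kind == "amplitude":
            mult[region] *= ratio
        elif eff.kind == "synchrony":
            # every region voxel follows one latent frequency/phase draw
            f_lat = rng.uniform(spec.band_low_hz, spec.band_high_hz, size=n_sin)
            p_lat = rng.uniform(0.0, 2.0 * np.pi, size=n_sin)
            freqs[region] = f_lat
            phases[region] = p_lat
            mult[region] *= ratio
        elif eff.kind == "hub":
            f_lat = rng.uniform(spec.band_low_hz, spec.band_high_hz, size=n_sin)
            p_lat = rng.uniform(0.0, 2.0 * np.pi, size=n_sin)
            course = _course(f_lat, p_lat)
            latent_add[region] += ratio * course
            latent_add[partners[i]] += spec.hub_partner_weight * course

    # second-order recurrence sin(w(t+1)+p) = 2cos(w) sin(wt+p) - sin(w(t-1)+p)
    # evaluates all voxel sinusoids without materializing a (V, S, T) tensor
    w = 2.0 * np.pi * freqs * spec.tr_s
    two_cos = 2.0 * np.cos(w)
    s_prev = np.sin(phases - w)
    s_cur = np.sin(phases)
    signal = np.empty((n_vox, n_t))
    signal[:, 0] = s_cur.sum(axis=1)
    for ti in range(1, n_t):
        s_prev, s_cur = s_cur, two_cos * s_cur - s_prev
        signal[:, ti] = s_cur.sum(axis=1)
    signal *= amp * mult[:, None]
    signal += latent_add

    noise_sd = spec.noise_sd * site_spec.noise_scale
    data = spec.baseline_mean + site_spec.offset + signal
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=(n_vox, n_t))
    brain, _, _ = tissue_masks(shape)
    vol = np.zeros(shape + (n_t,))
    vol.reshape(n_vox, n_t)[:] = data
    vol[~brain] = 0.0
    return BoldSeries(vol, spec.tr_s, analysis_mask(shape), affine=spec.affine)


def generate_motion_trace(n_volumes: int, severity: float, seed: int,
                          subject_index: int = 0) -> MotionTrace:
    """Random-walk 6-parameter trace; severity 0 gives an all-zero trace.

    Translation steps have SD ``severity`` mm; rotation steps SD
    ``severity / 50`` rad so both contribute comparably to FD at the 50 mm
    head radius.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if severity == 0:
        return MotionTrace(np.zeros((n_volumes, 6)))
    rng = _rng(seed, _STREAM_MOTION, subject_index)
    steps = rng.normal(0.0, severity, size=(n_volumes, 6))
    steps[:, 3:] /= 50.0
    steps[0] = 0.0
    return MotionTrace(np.cumsum(steps, axis=0))


def _effect_multipliers(spec: CohortSpec, group: str) -> list[float]:
    return [eff.group_ratio if group == "reverter" else 1.0 for eff in spec.effects]


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectSim], pd.DataFrame]:
    """All subjects plus the covariate table.

    Subjects of each group are distributed round-robin over the sites whose
    ``groups`` tuple admits them, so by default every site sees both groups;
    restricting a site to one group exercises the site-coverage filter.
    """
    brain, wm, csf = tissue_masks(spec.grid_shape)
    demo_rng = _rng(spec.seed, _STREAM_COHORT, 99)
    subjects: list[SubjectSim] = []
    rows = []
    idx = 0
    for group in GROUPS:
        eligible = [s.name for s in spec.sites if group in s.groups]
        if not eligible:
            raise ValueError(f"no site admits group {group!r}")
        for j in range(spec.n_per_group):
            site = eligible[j % len(eligible)]
            sid = f"sub-{group[0]}{j + 1:02d}"
            bold = generate_bold_subject(spec, group, site, idx)
            motion = generate_motion_trace(spec.n_volumes, spec.motion_severity,
                                           spec.seed, idx)
            subj = SubjectSim(
                subject_id=sid, group=group, site=site, bold=bold, motion=motion,
                brain_mask=brain, wm_mask=wm, csf_mask=csf,
                effect_multipliers=_effect_multipliers(spec, group),
                age=float(np.round(demo_rng.normal(74.0, 7.0), 1)),
                sex="M" if demo_rng.random() < 0.55 else "F",
                education=float(np.round(demo_rng.normal(16.7, 2.4), 1)),
            )
            subjects.append(subj)
            rows.append({"subject_id": sid, "group": group, "site": site,
                         "age": subj.age, "sex": subj.sex,
                         "education": subj.education})
            idx += 1
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavioural scores
# ---------------------------------------------------------------------------

def planted_magnitudes(subjects: list[SubjectSim], effect_index: int = 0) -> np.ndarray:
    """Per-subject true planted multiplier for one effect region."""
    return np.array([s.effect_multipliers[effect_index] for s in subjects])


def generate_behavioral_scores(magnitudes, slope: float = 1.0,
                               intercept: float = 0.0, noise_sd: float = 0.0,
                               seed: int = 0) -> np.ndarray:
    """Scores linear in the per-subject effect magnitude plus Gaussian noise."""
    m = np.asarray(magnitudes, dtype=float)
    rng = _rng(seed, _STREAM_SCORES)
    noise = rng.normal(0.0, noise_sd, size=m.shape) if noise_sd > 0 else 0.0
    return intercept + slope * m + noise


def behavioral_score_table(subjects: list[SubjectSim],
                           associations: dict[str, tuple[int, float]],
                           noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Named scale columns, each tied to (effect_index, slope)."""
    rng = _rng(seed, _STREAM_SCORES, 1)
    out = {"subject_id": [s.subject_id for s in subjects]}
    for scale, (eff_idx, slope) in associations.items():
        m = planted_magnitudes(subjects, eff_idx)
        noise = rng.normal(0.0, noise_sd, size=m.shape) if noise_sd > 0 else 0.0
        out[scale] = slope * m + noise
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# On-disk layout (NIfTI + SPM-style rp_*.txt + CSV)
# ---------------------------------------------------------------------------

def save_nifti_deterministic(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    """Write NIfTI; .gz output is compressed with mtime=0 for bit-stable bytes."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if path.suffix == ".gz":
        buf = io.BytesIO()
        file_map = img.make_file_map({"image": buf, "header": buf})
        img.to_file_map(file_map)
        path.write_bytes(gzip.compress(buf.getvalue(), mtime=0))
    else:
        nib.save(img, str(path))


def write_cohort(subjects: list[SubjectSim], table: pd.DataFrame,
                 outdir: str | Path) -> list[Path]:
    """Emit <sub>_bold.nii.gz, rp_<sub>.txt, shared masks and participants.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    first = subjects[0]
    for name, m in (("brain_mask", first.brain_mask), ("wm_mask", first.wm_mask),
                    ("csf_mask", first.csf_mask)):
        p = outdir / f"{name}.nii.gz"
        save_nifti_deterministic(m.astype(np.uint8), first.bold.affine, p)
        written.append(p)
    for s in subjects:
        p = outdir / f"{s.subject_id}_bold.nii.gz"
        save_nifti_deterministic(s.bold.data, s.bold.affine, p)
        written.append(p)
        rp = outdir / f"rp_{s.subject_id}.txt"
        s.motion.to_file(rp)
        written.append(rp)
    csv = outdir / "participants.csv"
    table.to_csv(csv, index=False)
    written.append(csv)
    return written
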