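"""Ground-truth-known synthetic data for the three quantification streams.

The generators invert the measurement models used downstream:

* :func:`simulate_larva` builds a peristaltic crawler whose spine length
  oscillates as one cosine per contraction cycle, so the smoothed
  derivative of spine length has a positive-going zero crossing exactly at
  each cycle boundary; the centroid advances a known stride per cycle and
  carries a lateral wobble calibrated so the realized path rate equals the
  requested walking rate.
* :func:`simulate_fish_stack` builds a two-channel 3D stack with one
  nascent-transcription focus per nucleus per channel, co-located at the
  nucleus centre, with a known per-nucleus col/nau intensity ratio.
* :func:`sample_phenotypes` draws per-segment muscle phenotype calls from
  fixed multinomial proportions.

Every generator takes an integer seed and is bit-reproducible.  Sub-seeds
for collections are derived with :func:`subseed` (a spawn-key counter
scheme), so regeneration is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import CHANNEL_NAMES, ImageStack, NucleusMaskSet, SpineTrack

PHENOTYPE_CATEGORIES = ("normal", "branched", "transformed", "absent")


def subseed(seed: int, index: int) -> int:
    """Derive the index-th child seed of ``seed`` (deterministic, < 2**31)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Crawling kinematics


@dataclass
class KinematicParams:
    """Generating parameters of a peristaltic crawler.

    Units: mm, s, radians.  ``walking_rate_mean`` is the mean per-frame
    centroid path rate and must be at least ``stride_length_mean /
    stride_duration_mean`` (the net advance rate); the surplus is realised
    as lateral wobble.  SDs are per-cycle draws; there is no between-larva
    random effect.
    """

    walking_rate_mean: float = 1.15
    stride_length_mean: float = 1.17
    stride_length_sd: float = 0.26
    stride_duration_mean: float = 1.09
    stride_duration_sd: float = 0.152
    heading_sd: float = 0.15
    fps: float = 5.0
    duration: float = 20.0
    pause_prob: float = 0.0
    pause_duration: float = 1.0
    # resting spine length and fractional contraction amplitude
    spine_length_rest: float = 4.0
    contraction_amplitude: float = 0.15

    def validate(self) -> None:
        if min(self.walking_rate_mean, self.stride_length_mean,
               self.stride_duration_mean) <= 0:
            raise ValueError("rate, stride length and duration means must be > 0")
        if self.stride_length_sd < 0 or self.stride_duration_sd < 0 or self.heading_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be > 0")
        net_rate = self.stride_length_mean / self.stride_duration_mean
        if self.walking_rate_mean < net_rate * (1 - 1e-12):
            raise ValueError(
                f"walking_rate_mean ({self.walking_rate_mean}) cannot be below "
                f"stride_length/stride_duration ({net_rate:.4f}): the lateral "
                "wobble amplitude would be imaginary"
            )
        if not 0 <= self.pause_prob <= 1:
            raise ValueError("pause_prob must be in [0, 1]")
        if not 0 < self.contraction_amplitude < 1:
            raise ValueError("contraction_amplitude must be in (0, 1)")


def _draw_cycles(params: KinematicParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw cycle (and pause) intervals covering the whole record."""
    t = 0.0
    rows = []
    heading = rng.uniform(0, 2 * np.pi)
    while t < params.duration:
        # truncated draws: duration >= half its mean, stride > 0
        while True:
            T = rng.normal(params.stride_duration_mean, params.stride_duration_sd)
            if T >= 0.5 * params.stride_duration_mean:
                break
        while True:
            S = rng.normal(params.stride_length_mean, params.stride_length_sd)
            if S > 0:
                break
        rows.append({"kind": "cycle", "t_start": t, "T": T, "S": S,
                     "heading": heading})
        t += T
        if params.pause_prob > 0 and rng.uniform() < params.pause_prob:
            rows.append({"kind": "pause", "t_start": t, "T": params.pause_duration,
                         "S": 0.0, "heading": heading})
            t += params.pause_duration
        heading = heading + rng.normal(0.0, params.heading_sd)
    df = pd.DataFrame(rows)
    df["t_end"] = df["t_start"] + df["T"]
    return df


def _base_trajectory(cycles: pd.DataFrame, times: np.ndarray,
                     params: KinematicParams):
    """Per-frame centroid base path, spine length and heading (no wobble)."""
    n = len(times)
    base = np.zeros((n, 2))
    L = np.full(n, params.spine_length_rest)
    head = np.zeros(n)
    amp = params.contraction_amplitude * params.spine_length_rest

    # cumulative start positions of each interval
    starts = np.zeros((len(cycles), 2))
    pos = np.zeros(2)
    for j, row in cycles.iterrows():
        starts[j] = pos
        if row["kind"] == "cycle":
            h = np.array([np.cos(row["heading"]), np.sin(row["heading"])])
            pos = pos + row["S"] * h
    idx = np.searchsorted(cycles["t_end"].to_numpy(), times, side="right")
    idx = np.clip(idx, 0, len(cycles) - 1)
    for k in range(n):
        row = cycles.iloc[idx[k]]
        phi = (times[k] - row["t_start"]) / row["T"]
        phi = min(max(phi, 0.0), 1.0)
        head[k] = row["heading"]
        if row["kind"] == "cycle":
            h = np.array([np.cos(row["heading"]), np.sin(row["heading"])])
            base[k] = starts[idx[k]] + row["S"] * phi * h
            L[k] = params.spine_length_rest - amp * np.cos(2 * np.pi * phi)
        else:  # pause: frozen at interval start, spine at boundary length
            base[k] = starts[idx[k]]
            L[k] = params.spine_length_rest - amp
    return base, L, head


def _solve_wobble(base: np.ndarray, head: np.ndarray, fps: float,
                  rate_surplus: float) -> float:
    """Wobble amplitude adding ``rate_surplus`` to the realized path rate.

    The centroid is ``base + w * (-1)**k * n_hat(k)`` with ``n_hat`` the
    unit normal to the current heading.  The wobble models the lateral
    body sway that makes the centroid path rate exceed the net advance
    rate; its per-larva amplitude is solved so the realized mean per-frame
    step rate equals the larva's realized net rate plus the parameter-level
    surplus ``walking_rate_mean - stride_length_mean/stride_duration_mean``.
    Tying the target to the realized net rate keeps the calibration
    feasible for every draw and the cohort mean unbiased; the mean step
    rate is continuous and strictly increasing in ``w``, so a bounded
    scalar root find pins it exactly (up to solver tolerance).
    """
    if rate_surplus < 0:
        raise ValueError("rate surplus must be >= 0")
    normals = np.stack([-np.sin(head), np.cos(head)], axis=1)
    signs = np.where(np.arange(len(base)) % 2 == 0, 1.0, -1.0)[:, None]

    def mean_rate(w: float) -> float:
        p = base + w * signs * normals
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).mean() * fps)

    target_rate = mean_rate(0.0) + rate_surplus
    if rate_surplus < 1e-12:
        return 0.0
    hi = target_rate / fps
    while mean_rate(hi) < target_rate:
        hi *= 2.0
    return float(brentq(lambda w: mean_rate(w) - target_rate, 0.0, hi,
                        xtol=1e-12))


def simulate_larva(params: KinematicParams, seed: int,
                   larva_id: str = "larva", genotype: str = "") -> SpineTrack:
    """Simulate one crawling larva; returns a :class:`SpineTrack`.

    The track's ``truth`` attribute records the generating per-cycle table
    (t_start, t_end, T, S, heading) plus the solved wobble amplitude.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n_frames = int(round(params.duration * params.fps))
    times = np.arange(n_frames) / params.fps

    cycles = _draw_cycles(params, rng)
    base, L, head = _base_trajectory(cycles, times, params)
    surplus = (params.walking_rate_mean
               - params.stride_length_mean / params.stride_duration_mean)
    w = _solve_wobble(base, head, params.fps, max(surplus, 0.0))

    normals = np.stack([-np.sin(head), np.cos(head)], axis=1)
    signs = np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)[:, None]
    centroid = base + w * signs * normals

    # straight spine through the centroid along the heading, head first
    h_vec = np.stack([np.cos(head), np.sin(head)], axis=1)
    offsets = np.array([2.0, 1.0, 0.0, -1.0, -2.0])  # quarter-lengths
    points = centroid[:, None, :] + (offsets[None, :, None] *
                                     (L[:, None, None] / 4.0) * h_vec[:, None, :])

    truth = cycles.copy()
    truth.attrs["wobble"] = w
    return SpineTrack(larva_id=larva_id, fps=params.fps, points=points,
                      genotype=genotype, truth=truth)


def simulate_cohort(n: int, params: KinematicParams, seed: int,
                    genotype: str = "") -> Tuple[list, pd.DataFrame]:
    """Simulate ``n`` independent larvae with reproducible per-larva sub-seeds.

    Returns (tracks, metadata) where metadata has columns larva_id,
    genotype, seed.  Sub-seeds depend only on (seed, index), so the cohort
    is invariant to generation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tracks, meta = [], []
    for i in range(n):
        s = subseed(seed, i)
        lid = f"{genotype or 'larva'}_{i:03d}"
        tracks.append(simulate_larva(params, s, larva_id=lid, genotype=genotype))
        meta.append({"larva_id": lid, "genotype": genotype, "seed": s})
    return tracks, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# Two-channel FISH stacks


@dataclass
class FishGenParams:
    """Generating parameters for a two-channel nascent-transcript stack.

    One focus per nucleus per channel, both at the nucleus centre; the
    col focus amplitude is ``R_i * nau_amplitude_mean`` with
    ``R_i ~ Normal(ratio_mean, ratio_sd)`` truncated positive.  Intensities
    are arbitrary camera units.
    """

    n_nuclei: int = 28
    ratio_mean: float = 2.2
    ratio_sd: float = 0.26
    nau_amplitude_mean: float = 100000.0
    background_level: float = 20.0
    psf_sigma: float = 1.5
    noise_model: Union[str, Tuple[str, float]] = "poisson"
    stack_shape: Tuple[int, int, int] = (16, 256, 256)
    n_channels: int = 2
    nucleus_radius_xy: float = 7.0
    nucleus_radius_z: float = 3.0
    mask_margin: float = 2.0

    def validate(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.ratio_mean <= 0 or self.ratio_sd < 0:
            raise ValueError("ratio_mean must be > 0 and ratio_sd >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.n_channels != 2:
            raise ValueError("exactly 2 channels (col, nau) are supported")
        if len(self.stack_shape) != 3:
            raise ValueError("stack_shape must be (z, y, x)")
        if self.noise_model not in ("poisson", "none") and not (
            isinstance(self.noise_model, (tuple, list))
            and len(self.noise_model) == 2
            and self.noise_model[0] == "gaussian"
        ):
            raise ValueError(
                "noise_model must be 'poisson', 'none' or ('gaussian', sd)"
            )


class PlacementError(RuntimeError):
    """Nuclei could not be placed without overlap."""


def _place_nuclei(params: FishGenParams, rng: np.random.Generator,
                  max_tries: int = 5000) -> np.ndarray:
    """Non-overlapping nucleus centres, returned as (n, 3) z, y, x."""
    nz, ny, nx = params.stack_shape
    r_xy = params.nucleus_radius_xy + params.mask_margin
    min_sep = 2.0 * r_xy + 1.0  # projected discs must not touch
    # foci carry a 4-sigma Gaussian kernel that must fit inside the stack
    kr = max(int(np.ceil(4 * params.psf_sigma)), 1)
    rz = max(params.nucleus_radius_z, kr)
    lo_z, hi_z = rz, nz - 1 - rz
    rb = max(r_xy, kr)
    if hi_z < lo_z or ny <= 2 * rb or nx <= 2 * rb:
        raise PlacementError("stack_shape too small for the nucleus size")
    centres = []
    for _ in range(params.n_nuclei):
        for _ in range(max_tries):
            z = rng.uniform(lo_z, hi_z)
            y = rng.uniform(rb, ny - 1 - rb)
            x = rng.uniform(rb, nx - 1 - rb)
            if all((y - c[1]) ** 2 + (x - c[2]) ** 2 >= min_sep**2
                   for c in centres):
                centres.append((z, y, x))
                break
        else:
            raise PlacementError(
                f"could not place {params.n_nuclei} non-overlapping nuclei "
                f"in stack_shape {params.stack_shape}"
            )
    # snap to voxel grid so focus placement is exact
    return np.rint(np.array(centres)).astype(int)


def _gaussian_kernel3d(sigma: float) -> np.ndarray:
    """Discrete 3D Gaussian summing to 1, truncated at 4 sigma."""
    r = max(int(np.ceil(4 * sigma)), 1)
    ax = np.arange(-r, r + 1)
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return k / k.sum()


def simulate_fish_stack(params: FishGenParams, seed: int,
                        group: str = ""):
    """Simulate a two-channel FISH stack with nuclear masks and ground truth.

    Returns (ImageStack, NucleusMaskSet, truth) where ``truth`` is a
    DataFrame with one row per nucleus: nucleus_id, ratio_true, amp_col,
    amp_nau and the focus centre.  Before noise, the background-subtracted
    integrated focus ratio in each nuclear ROI equals ratio_true exactly.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.stack_shape
    centres = _place_nuclei(params, rng)

    ratios = np.empty(params.n_nuclei)
    for i in range(params.n_nuclei):
        while True:
            r = rng.normal(params.ratio_mean, params.ratio_sd)
            if r > 0:
                ratios[i] = r
                break

    clean = np.full((2, nz, ny, nx), float(params.background_level))
    kernel = _gaussian_kernel3d(params.psf_sigma)
    kr = kernel.shape[0] // 2
    i_col = CHANNEL_NAMES.index("col")
    i_nau = CHANNEL_NAMES.index("nau")

    labels = np.zeros((ny, nx), dtype=np.int64)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rows = []
    r_mask = params.nucleus_radius_xy + params.mask_margin
    for i, (cz, cy, cx) in enumerate(centres):
        nucleus_id = i + 1
        amp_nau = params.nau_amplitude_mean
        amp_col = ratios[i] * amp_nau
        sl = (slice(cz - kr, cz + kr + 1), slice(cy - kr, cy + kr + 1),
              slice(cx - kr, cx + kr + 1))
        clean[i_col][sl] += amp_col * kernel
        clean[i_nau][sl] += amp_nau * kernel
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_mask**2] = nucleus_id
        rows.append({"nucleus_id": nucleus_id, "ratio_true": ratios[i],
                     "amp_col": amp_col, "amp_nau": amp_nau,
                     "z": cz, "y": cy, "x": cx, "group": group})

    noisy = _apply_noise(clean, params.noise_model, rng)
    truth = pd.DataFrame(rows)
    return ImageStack(pixels=noisy), NucleusMaskSet(labels=labels), truth


def _apply_noise(clean: np.ndarray, model, rng: np.random.Generator) -> np.ndarray:
    if model == "none":
        return clean
    if model == "poisson":
        return rng.poisson(clean).astype(float)
    kind, sd = model
    return np.clip(clean + rng.normal(0.0, sd, size=clean.shape), 0.0, None)


# ---------------------------------------------------------------------------
# Phenotype calls


@dataclass
class PhenotypeProportions:
    """Multinomial proportions over the four DA3 phenotype categories."""

    p_normal: float
    p_branched: float
    p_transformed: float
    p_absent: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_normal, self.p_branched,
                         self.p_transformed, self.p_absent])

    def validate(self) -> None:
        p = self.as_array()
        if (p < 0).any() or (p > 1).any():
            raise ValueError("proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")


def sample_phenotypes(props: PhenotypeProportions, n_segments: int, seed: int,
                      genotype: str = "") -> pd.DataFrame:
    """Draw i.i.d. per-segment phenotype calls.

    Returns a table with columns embryo_id, segment_id (A1..A7, cycling),
    genotype, category — one row per scored hemisegment.
    """
    props.validate()
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(PHENOTYPE_CATEGORIES), size=n_segments,
                       p=props.as_array())
    rows = [{
        "embryo_id": f"{genotype or 'embryo'}_{k // 7:03d}",
        "segment_id": f"A{k % 7 + 1}",
        "genotype": genotype,
        "category": PHENOTYPE_CATEGORIES[d],
    } for k, d in enumerate(draws)]
    return pd.DataFrame(rows)
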