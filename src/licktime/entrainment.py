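"""Entrainment of spiking to the lick cycle.

Pipeline: keep licks from rhythmic runs (>= 3 consecutive licks, every
inter-lick interval within 100-175 ms), assign each spike inside a retained
lick pair a phase by linear interpolation (tongue contact = 0 = 2*pi),
summarize phases by the mean resultant, test circular uniformity with a
Rayleigh test, and control the population screen at FDR 0.05 with
Benjamini-Hochberg. Phase distributions are displayed as 20-bin histograms
(bin width pi/10) and wrapped-kernel densities (width 0.3) thresholded at
1.02/(2*pi).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import EntrainmentResult, InsufficientDataError, _as_sorted_times

RHYTHMIC_ILI_S = (0.100, 0.175)
MIN_RUN_LICKS = 3
N_HIST_BINS = 20                    # bin width pi/10
KERNEL_WIDTH = 0.3
DENSITY_THRESHOLD = 1.02 / (2.0 * np.pi)
DEFAULT_GRID = 360


def select_rhythmic_licks(licks) -> list[np.ndarray]:
    """Maximal runs of >= 3 licks whose every internal ILI lies in
    [0.100, 0.175] s (inclusive bounds)."""
    t = _as_sorted_times(licks, "licks")
    if t.size < MIN_RUN_LICKS:
        return []
    lo, hi = RHYTHMIC_ILI_S
    ok = (np.diff(t) >= lo) & (np.diff(t) <= hi)
    runs = []
    i = 0
    while i < ok.size:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < ok.size and ok[j]:
            j += 1
        if (j - i + 1) >= MIN_RUN_LICKS:      # licks in run = ILIs + 1
            runs.append(t[i : j + 1])
        i = j
    return runs


def spike_phases(spike_times, rhythmic_runs: Sequence[np.ndarray]) -> np.ndarray:
    """Lick-cycle phase of each spike falling inside a retained lick pair:
    phase = 2*pi*(t - t_prev)/(t_next - t_prev), in [0, 2*pi). Spikes in
    gaps between retained runs are dropped."""
    spikes = np.asarray(spike_times, dtype=float)
    phases = []
    for run in rhythmic_runs:
        lo_i, hi_i = np.searchsorted(spikes, [run[0], run[-1]])
        s = spikes[lo_i:hi_i]
        if s.size == 0:
            continue
        idx = np.searchsorted(run, s, side="right") - 1
        idx = np.clip(idx, 0, run.size - 2)
        phi = 2.0 * np.pi * (s - run[idx]) / (run[idx + 1] - run[idx])
        phases.append(phi)
    if not phases:
        return np.empty(0)
    out = np.concatenate(phases)
    return np.mod(out, 2.0 * np.pi)


def mean_resultant(phases) -> tuple[float, float]:
    """(length, angle) of the mean resultant vector; angle in [0, 2*pi)."""
    phi = np.asarray(phases, dtype=float)
    if phi.size == 0:
        raise InsufficientDataError("mean_resultant requires >= 1 phase")
    z = np.exp(1j * phi).mean()
    return float(np.abs(z)), float(np.mod(np.angle(z), 2.0 * np.pi))


def rayleigh_test(phases) -> float:
    """Rayleigh test of circular uniformity, Wilkie's finite-n corrected
    approximation: p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with
    Rn = n * mean resultant length."""
    phi = np.asarray(phases, dtype=float)
    n = phi.size
    if n == 0:
        raise InsufficientDataError("rayleigh_test requires >= 1 phase")
    rbar, _ = mean_resultant(phi)
    rn = n * rbar
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def bh_select_entrained(
    p_values, fdr: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up across units: (flags, q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, bool), np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject.astype(bool), q


def phase_histogram(phases, n_bins: int = N_HIST_BINS) -> np.ndarray:
    """Counts over [0, 2*pi) in ``n_bins`` equal bins (default width pi/10)."""
    phi = np.mod(np.asarray(phases, dtype=float), 2.0 * np.pi)
    counts, _ = np.histogram(phi, bins=n_bins, range=(0.0, 2.0 * np.pi))
    return counts


def circular_density(
    phases,
    kernel_width: float = KERNEL_WIDTH,
    grid_size: int = DEFAULT_GRID,
    kernel: str = "wrapped_gaussian",
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density of phases on a uniform grid over [0, 2*pi),
    normalized to unit mass on the circle.

    ``wrapped_gaussian`` treats ``kernel_width`` as the Gaussian sigma in
    radians (the angular distance is wrapped to [-pi, pi), which captures
    all wrap terms for widths well below pi); ``von_mises`` uses
    concentration kappa = 1/kernel_width**2.
    """
    phi = np.mod(np.asarray(phases, dtype=float), 2.0 * np.pi)
    if phi.size == 0:
        raise InsufficientDataError("circular_density requires >= 1 phase")
    grid = 2.0 * np.pi * np.arange(grid_size) / grid_size
    d = grid[:, None] - phi[None, :]
    d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    if kernel == "wrapped_gaussian":
        k = np.exp(-0.5 * (d / kernel_width) ** 2)
    elif kernel == "von_mises":
        kappa = 1.0 / kernel_width**2
        k = np.exp(kappa * np.cos(d))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    density = k.mean(axis=1)
    density /= density.sum() * (2.0 * np.pi / grid_size)
    return grid, density


def threshold_density(
    density, threshold: float = DENSITY_THRESHOLD
) -> np.ndarray:
    """Mask of grid points where the density exceeds 1.02/(2*pi): phases at
    which spiking is (2%) denser than the uniform rate."""
    return np.asarray(density, dtype=float) > threshold


def analyze_unit(
    unit_id: str,
    spike_times,
    licks,
    *,
    kernel_width: float = KERNEL_WIDTH,
    grid_size: int = DEFAULT_GRID,
) -> EntrainmentResult:
    """Full single-unit entrainment analysis (without the population BH
    step, which needs every unit's p-value)."""
    runs = select_rhythmic_licks(licks)
    phi = spike_phases(spike_times, runs)
    if phi.size == 0:
        return EntrainmentResult(
            unit_id=unit_id,
            n_spikes=0,
            resultant_length=float("nan"),
            resultant_angle=float("nan"),
            rayleigh_p=float("nan"),
        )
    r, ang = mean_resultant(phi)
    p = rayleigh_test(phi)
    grid, dens = circular_density(phi, kernel_width, grid_size)
    return EntrainmentResult(
        unit_id=unit_id,
        n_spikes=int(phi.size),
        resultant_length=r,
        resultant_angle=ang,
        rayleigh_p=p,
        histogram=phase_histogram(phi),
        density_grid=grid,
        density=dens,
        suprathreshold_mask=threshold_density(dens),
    )


def analyze_population(
    spike_trains: dict[str, np.ndarray], licks, fdr: float = 0.05
) -> list[EntrainmentResult]:
    """Per-unit entrainment plus the BH screen at the given FDR. Units with
    no phase-assignable spikes keep NaN statistics and are never flagged.
    Results are sorted by unit_id (the deterministic tie-break for the
    population displays)."""
    results = [
        analyze_unit(uid, spikes, licks)
        for uid, spikes in sorted(spike_trains.items())
    ]
    testable = [r for r in results if np.isfinite(r.rayleigh_p)]
    if testable:
        flags, q = bh_select_entrained([r.rayleigh_p for r in testable], fdr)
        for r, f, qv in zip(testable, flags, q):
            r.entrained = bool(f)
            r.q_value = float(qv)
    return results
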