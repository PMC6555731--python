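"""Synthetic inputs for every pipeline stage.

The generators here emulate the data the analyses consume, with planted
ground truth so every estimator can be checked against a known answer:

* per-gene log2-fold-change tables with a configurable median shift delta
  planted on designated gene sets over a null (zero-median Gaussian)
  background — the synthetic counterpart of a differential-expression
  program's output table;
* striated intensity line profiles and 2-D images with a known spatial
  period, emulating Z-line fluorescence along a myotube;
* developmental differential-expression tables with fixed numbers of
  significantly up/down-regulated genes;
* TPM expression matrices in which a chosen subset of genes is expressed;
* gel-lane profiles built from Gaussian bands of known integrated amount on
  a smooth baseline.

Every generator is a pure function of its config, including the mandatory
seed: the same config always yields byte-identical output.  There is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .densitometry import LaneProfile
from .errors import ValidationError
from .geneset import DeTable, GeneSet, LfcTable
from .morphometry import IntensityProfile


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _gene_ids(start: int, n: int) -> list[str]:
    return [f"gene{i:06d}" for i in range(start, start + n)]


# ---------------------------------------------------------------------------
# LFC tables with planted gene-set shifts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LfcSimConfig:
    """Simulated LFC table: null background plus shifted gene sets.

    ``delta`` may be a single shift applied to every set or a map of
    set-name -> shift (log2 units).  ``sigma`` is the per-gene LFC standard
    deviation shared by background and set genes.  Sets are built from
    disjoint identifier ranges, so they never overlap.
    """

    n_background_genes: int
    set_sizes: Mapping[str, int]
    delta: float | Mapping[str, float]
    sigma: float
    seed: int
    comparison_label: str = "simulated"

    def __post_init__(self):
        if self.n_background_genes < 1:
            raise ValidationError("n_background_genes must be >= 1")
        if not (self.sigma > 0):
            raise ValidationError("sigma must be positive")
        if len(self.set_sizes) == 0:
            raise ValidationError("at least one gene set must be configured")
        for name, size in self.set_sizes.items():
            if size < 1:
                raise ValidationError(f"set {name!r} must have >= 1 gene")
        object.__setattr__(self, "set_sizes", dict(self.set_sizes))

    def delta_for(self, set_name: str) -> float:
        if isinstance(self.delta, Mapping):
            if set_name not in self.delta:
                raise ValidationError(f"no delta configured for set {set_name!r}")
            return float(self.delta[set_name])
        return float(self.delta)


def simulate_lfc_table(config: LfcSimConfig) -> tuple[LfcTable, dict[str, GeneSet]]:
    """Draw an LFC table with a planted median shift per configured set.

    Background LFCs are N(0, sigma^2) (zero-median, symmetric); each set's
    LFCs are N(delta_set, sigma^2).  q-values are uniform placeholders — the
    shift statistics never read them.
    """
    rng = _rng(config.seed)
    ids: list[str] = _gene_ids(0, config.n_background_genes)
    lfcs = [rng.normal(0.0, config.sigma, config.n_background_genes)]
    sets: dict[str, GeneSet] = {}
    cursor = config.n_background_genes
    for name in config.set_sizes:  # insertion order: deterministic
        size = config.set_sizes[name]
        set_ids = _gene_ids(cursor, size)
        cursor += size
        ids.extend(set_ids)
        lfcs.append(rng.normal(config.delta_for(name), config.sigma, size))
        sets[name] = GeneSet(name, frozenset(set_ids))
    lfc = np.concatenate(lfcs)
    qval = rng.uniform(0.0, 1.0, lfc.size)
    table = LfcTable(
        pd.DataFrame({"gene_id": ids, "lfc": lfc, "qval": qval}),
        comparison_label=config.comparison_label,
    )
    return table, sets


# ---------------------------------------------------------------------------
# Striated profiles and images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StriationSimConfig:
    """A noisy cosine striation pattern with known spatial period."""

    period_um: float
    pixel_size_um: float
    n_samples: int
    amplitude: float = 100.0
    noise_sd: float = 0.0
    baseline: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")
        if not (self.period_um > 2 * self.pixel_size_um):
            raise ValidationError(
                f"period {self.period_um} um violates Nyquist at pixel size "
                f"{self.pixel_size_um} um"
            )
        if self.n_samples * self.pixel_size_um < 2 * self.period_um:
            raise ValidationError("profile must span >= 2 periods")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_striation_profile(config: StriationSimConfig) -> IntensityProfile:
    """baseline + amplitude*cos(2*pi*x/period) + N(0, noise_sd^2) per sample."""
    rng = _rng(config.seed)
    x = np.arange(config.n_samples) * config.pixel_size_um
    y = config.baseline + config.amplitude * np.cos(2 * np.pi * x / config.period_um)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, config.n_samples)
    return IntensityProfile(y, config.pixel_size_um)


def simulate_striation_image(
    config: StriationSimConfig, width_px: int, orientation_deg: float = 0.0
) -> np.ndarray:
    """2-D striation image: sinusoidal along ``orientation_deg``, constant
    perpendicular to it.

    Orientation 0 varies along +x; the image has ``width_px`` rows and
    ``config.n_samples`` columns.  Noise, if any, is per-pixel.
    """
    if width_px < 1:
        raise ValidationError("width_px must be >= 1")
    rng = _rng(config.seed)
    theta = np.deg2rad(orientation_deg)
    yy, xx = np.mgrid[0:width_px, 0:config.n_samples]
    d_um = (xx * np.cos(theta) + yy * np.sin(theta)) * config.pixel_size_um
    img = config.baseline + config.amplitude * np.cos(2 * np.pi * d_um / config.period_um)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return img


# ---------------------------------------------------------------------------
# Developmental DE tables and TPM matrices
# ---------------------------------------------------------------------------

def simulate_invivo_de_table(
    n_up: int,
    n_down: int,
    n_null: int,
    q_threshold: float = 0.05,
    seed: int = 0,
    lfc_scale: float = 1.0,
) -> DeTable:
    """A DE table with exact counts of significant up/down and null genes.

    Significant rows draw q uniformly on [0, q_threshold) and null rows on
    [q_threshold, 1]; q magnitudes carry no meaning beyond the threshold.
    Up/down rows have strictly positive/negative LFC.
    """
    if min(n_up, n_down, n_null) < 0:
        raise ValidationError("counts must be >= 0")
    if not (0 < q_threshold < 1):
        raise ValidationError("q_threshold must lie in (0, 1)")
    rng = _rng(seed)
    n = n_up + n_down + n_null
    ids = _gene_ids(0, n)
    lfc = np.empty(n)
    qval = np.empty(n)
    lfc[:n_up] = np.abs(rng.normal(lfc_scale, lfc_scale / 2, n_up)) + 1e-3
    lfc[n_up : n_up + n_down] = -(np.abs(rng.normal(lfc_scale, lfc_scale / 2, n_down)) + 1e-3)
    lfc[n_up + n_down :] = rng.normal(0.0, lfc_scale / 2, n_null)
    qval[: n_up + n_down] = rng.uniform(0.0, q_threshold, n_up + n_down)
    qval[n_up + n_down :] = rng.uniform(q_threshold, 1.0, n_null)
    return DeTable(
        pd.DataFrame({"gene_id": ids, "lfc": lfc, "qval": qval}),
        comparison_label="invivo_P2_vs_E18_simulated",
    )


def simulate_tpm_matrix(
    gene_ids: list[str],
    n_samples: int,
    expressed_ids: set[str] | frozenset[str],
    expressed_tpm: float = 50.0,
    silent_tpm: float = 0.01,
    dispersion: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """TPM matrix (genes x samples) where a chosen gene subset is expressed.

    Expressed genes draw log-normal TPM around ``expressed_tpm``; the rest sit
    near ``silent_tpm``, far below any sensible expression threshold.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = _rng(seed)
    means = np.where(
        np.isin(np.asarray(gene_ids, dtype=object), list(expressed_ids)),
        expressed_tpm, silent_tpm,
    ).astype(float)
    vals = means[:, None] * rng.lognormal(0.0, dispersion, (len(gene_ids), n_samples))
    cols = [f"sample{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"), columns=cols)


# ---------------------------------------------------------------------------
# Gel lanes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LaneSimConfig:
    """Gel lane: Gaussian bands of known integrated amount on a flat baseline.

    ``band_centers`` are fractions of the lane length in (0, 1);
    ``band_amounts`` are the true integrated (summed) intensities of each
    band; ``band_width`` is the Gaussian sigma in samples.
    """

    band_centers: tuple[float, ...]
    band_amounts: tuple[float, ...]
    band_width: float = 4.0
    baseline_level: float = 0.0
    noise_sd: float = 0.0
    n_samples: int = 512
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "band_centers", tuple(self.band_centers))
        object.__setattr__(self, "band_amounts", tuple(self.band_amounts))
        if len(self.band_centers) != len(self.band_amounts):
            raise ValidationError("band_centers and band_amounts differ in length")
        if any(not (0 < c < 1) for c in self.band_centers):
            raise ValidationError("band_centers must lie in (0, 1)")
        if any(a < 0 for a in self.band_amounts):
            raise ValidationError("band_amounts must be >= 0")
        if not (self.band_width > 0):
            raise ValidationError("band_width must be positive")
        if self.n_samples < 16:
            raise ValidationError("n_samples must be >= 16")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_lane(config: LaneSimConfig, lane_id: str = "") -> LaneProfile:
    """Sum of Gaussian bands (each summing to its configured amount) on a
    constant baseline, plus optional Gaussian noise."""
    rng = _rng(config.seed)
    x = np.arange(config.n_samples, dtype=float)
    y = np.full(config.n_samples, float(config.baseline_level))
    for center_frac, amount in zip(config.band_centers, config.band_amounts):
        c = center_frac * config.n_samples
        kernel = np.exp(-0.5 * ((x - c) / config.band_width) ** 2)
        s = kernel.sum()
        if s > 0 and amount > 0:
            y += amount * kernel / s
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, config.n_samples)
    return LaneProfile(y, lane_id)
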