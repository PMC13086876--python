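"""Synthetic multi-channel fluorescence fields with ground truth.

The generator emulates the statistical structure that per-nucleus
pixel-intensity colocalization assumes: fields of non-overlapping,
roughly elliptical nuclei, each containing a small number of bright
nucleolar disks.  Channels are rendered as two-level (nucleoplasm vs
nucleolus) piecewise-constant images plus acquisition noise:

* ``dapi``   — bright across the nucleus, dimmer inside nucleoli
  (nucleoli largely exclude DNA, so the counterstain dips there);
* ``marker`` — a nucleolar marker such as UBF or fibrillarin, level
  ``m0`` in the nucleoplasm and ``m1 > m0`` inside nucleoli;
* ``query``  — the protein under study, diffuse level ``q0`` plus an
  enrichment ``f * dq`` inside nucleoli, where ``f`` in [0, 1] is the
  per-cell ground-truth enrichment;
* ``pcna``   — optional replication-pattern channel (homogeneous for
  non-S cells, peripheral/perinucleolar puncta for mid-S cells).

Because every compartment mask and per-cell parameter is returned as
:class:`GroundTruth`, downstream segmentation, scoring and phase
classification can be validated against known answers.  The module also
provides :func:`expected_pearson_two_level`, a closed-form oracle for
the population Pearson coefficient of a noisy two-level image pair.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .phase import PhaseParams, zone_mask

__all__ = [
    "SimulationConfig",
    "FieldImage",
    "GroundTruth",
    "PcnaPattern",
    "PlacementError",
    "generate_field",
    "generate_control_field",
    "generate_pcna_pattern",
    "expected_pearson_two_level",
]

CHANNEL_ORDER = ("dapi", "marker", "query", "pcna")


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails after bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic field.

    Intensity levels are in raw camera units of an unsigned image of
    ``bit_depth`` bits; geometric parameters are in pixels.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    nucleus_axes_range: tuple[float, float] = (14.0, 22.0)
    nucleoli_per_nucleus: int = 2
    nucleolar_area_fraction: float = 0.12
    background: float = 8.0
    dapi_level: float = 180.0
    dapi_nucleolar_factor: float = 0.4
    marker_levels: tuple[float, float] = (30.0, 150.0)
    query_diffuse: float = 80.0
    query_boost: float = 80.0
    enrichment: float = 1.0
    enrichment_per_nucleus: tuple[float, ...] | None = None
    noise_sigma: float | Mapping[str, float] = 8.0
    poisson_noise: bool = False
    bleedthrough: float = 0.0
    bit_depth: int = 8
    pixel_size: float = 0.08
    boundary_jitter: float = 0.05
    border_margin: int = 6
    border_nuclei: int = 0
    pcna_phases: tuple[str, ...] | str | None = None
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.nucleolar_area_fraction < 1.0):
            raise ValueError("nucleolar_area_fraction must lie in (0, 1)")
        if not (0.0 <= self.bleedthrough < 1.0):
            raise ValueError("bleedthrough must lie in [0, 1)")
        m0, m1 = self.marker_levels
        if m1 <= m0:
            raise ValueError("marker level inside nucleoli must exceed outside level")
        for name in ("background", "dapi_level", "query_diffuse", "query_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("enrichment must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.nucleus_axes_range[0] > self.nucleus_axes_range[1]:
            raise ValueError("nucleus_axes_range must be (min, max)")

    def sigma_for(self, role: str) -> float:
        if isinstance(self.noise_sigma, Mapping):
            return float(self.noise_sigma.get(role, 0.0))
        return float(self.noise_sigma)


@dataclass
class FieldImage:
    """Multi-channel 2D image with channel roles.

    ``channels`` maps role names (``dapi``, ``marker``, ``query``,
    ``pcna``) to equally-shaped 2D intensity arrays.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for role, chan in self.channels.items():
            if np.any(np.asarray(chan) < 0):
                raise ValueError(f"channel {role!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Simulator truth for one field."""

    nucleus_labels: np.ndarray            # int label image, 0 = background
    nucleolus_labels: np.ndarray          # nucleolar pixels carry their nucleus label
    enrichment: dict[int, float]          # per-nucleus true enrichment f
    phase: dict[int, str]                 # per-nucleus true phase (mid_S / non_S)
    axes: dict[int, tuple[float, float]]  # per-nucleus true semi-axes (a, b)
    pcna_centers: dict[int, np.ndarray]   # per-nucleus puncta centers, (k, 2) row/col
    config: SimulationConfig

    @property
    def n_nuclei(self) -> int:
        return int(self.nucleus_labels.max())

    def nucleus_mask(self, label: int) -> np.ndarray:
        return self.nucleus_labels == label

    def nucleolus_mask(self, label: int) -> np.ndarray:
        return self.nucleolus_labels == label


class PcnaPattern(NamedTuple):
    image: np.ndarray
    centers: np.ndarray  # (k, 2) array of row/col puncta centers; empty for non_S


# --------------------------------------------------------------------------
# geometry helpers

def _jittered_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ellipse with a smooth low-order radial perturbation of the boundary."""
    h, w = shape
    a, b = axes
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    rho = np.hypot(u, v)
    if jitter > 0:
        theta = np.arctan2(v, u)
        amp = rng.uniform(0.3, 1.0, size=3) * jitter / 3.0
        ph = rng.uniform(0, 2 * np.pi, size=3)
        bound = 1.0 + sum(
            amp[k] * np.sin((k + 2) * theta + ph[k]) for k in range(3)
        )
    else:
        bound = 1.0
    return rho <= bound


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator):
    """Sample non-overlapping nucleus centers/axes; bounded rejection sampling."""
    h, w = cfg.field_shape
    amin, amax = cfg.nucleus_axes_range
    placed: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    n_border = min(cfg.border_nuclei, cfg.n_nuclei)
    for i in range(cfg.n_nuclei):
        at_border = i < n_border
        for _ in range(cfg.max_place_tries):
            a = rng.uniform(amin, amax)
            b = rng.uniform(amin, amax)
            r = max(a, b) * (1.0 + cfg.boundary_jitter)
            if at_border:
                # center close enough to an edge that the nucleus is clipped
                side = rng.integers(4)
                off = rng.uniform(-0.5 * r, 0.5 * r)
                if side == 0:
                    cy, cx = off, rng.uniform(r, w - r)
                elif side == 1:
                    cy, cx = h - 1 - off, rng.uniform(r, w - r)
                elif side == 2:
                    cy, cx = rng.uniform(r, h - r), off
                else:
                    cy, cx = rng.uniform(r, h - r), w - 1 - off
            else:
                m = r + cfg.border_margin
                if 2 * m >= min(h, w):
                    raise PlacementError("nuclei too large for the field")
                cy = rng.uniform(m, h - 1 - m)
                cx = rng.uniform(m, w - 1 - m)
            ok = all(
                math.hypot(cy - pc[0], cx - pc[1])
                > r + max(pa) * (1.0 + cfg.boundary_jitter) + 2.0
                for pc, pa, _ in placed
            )
            if ok:
                placed.append(((cy, cx), (a, b), rng.uniform(0, np.pi)))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{cfg.n_nuclei} without overlap"
            )
    return placed


def _place_nucleoli(
    nucleus_mask: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Disks of total area ~ p * nucleus area, fully inside the nucleus."""
    from scipy import ndimage

    area = int(nucleus_mask.sum())
    n = cfg.nucleoli_per_nucleus
    if n == 0 or area == 0:
        return np.zeros_like(nucleus_mask)
    radius = math.sqrt(cfg.nucleolar_area_fraction * area / (n * math.pi))
    radius = max(radius, 1.5)
    interior = ndimage.binary_erosion(
        nucleus_mask, structure=np.ones((3, 3)), iterations=max(1, int(radius) + 2)
    )
    coords = np.argwhere(interior)
    if coords.size == 0:
        raise PlacementError("nucleus too small to host nucleoli")
    out = np.zeros_like(nucleus_mask)
    centers: list[tuple[int, int]] = []
    rr, cc = np.mgrid[0 : nucleus_mask.shape[0], 0 : nucleus_mask.shape[1]]
    min_sep = 2 * radius + 1
    while len(centers) < n:
        for _try in range(cfg.max_place_tries):
            cy, cx = coords[rng.integers(len(coords))]
            if all(math.hypot(cy - y, cx - x) > min_sep for y, x in centers):
                centers.append((cy, cx))
                out |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
                break
        else:
            # tight (e.g. border-clipped) nucleus: relax separation toward
            # touching disks, then accept fewer nucleoli rather than fail
            if min_sep > radius:
                min_sep = max(radius, 0.8 * min_sep)
                continue
            break
    return out & nucleus_mask


# --------------------------------------------------------------------------
# rendering

def _render_noise(
    clean: np.ndarray,
    sigma: float,
    poisson: bool,
    bit_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    img = clean.astype(float)
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape)
    top = 2**bit_depth - 1
    img = np.clip(np.rint(img), 0, top)
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    return img.astype(dtype)


def generate_field(
    config: SimulationConfig, *, positive_control: bool = False
) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic for a fixed ``config.seed``: one root seed sequence is
    spawned into named per-stage streams, with per-nucleus sub-streams,
    so identical configs give bit-identical images.

    With ``positive_control=True`` the query channel is replaced by an
    independent noisy re-rendering of the marker structure — the in
    silico analogue of staining one nucleolar protein with two secondary
    antibodies to probe the upper end of the assay's dynamic range.
    """
    cfg = config
    h, w = cfg.field_shape
    root = np.random.SeedSequence(cfg.seed)
    ss_place, ss_noise, ss_cells = root.spawn(3)
    rng_place = np.random.default_rng(ss_place)
    rng_noise = np.random.default_rng(ss_noise)

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    nucleolus_labels = np.zeros((h, w), dtype=np.int32)
    enrichment: dict[int, float] = {}
    phase: dict[int, str] = {}
    axes: dict[int, tuple[float, float]] = {}
    pcna_centers: dict[int, np.ndarray] = {}

    if cfg.enrichment_per_nucleus is not None and len(
        cfg.enrichment_per_nucleus
    ) != cfg.n_nuclei:
        raise ValueError("enrichment_per_nucleus length must equal n_nuclei")

    placements = _place_nuclei(cfg, rng_place)
    cell_seeds = ss_cells.spawn(max(cfg.n_nuclei, 1))

    phases = _resolve_phases(cfg)

    clean = {
        role: np.full((h, w), cfg.background, dtype=float)
        for role in ("dapi", "marker", "query")
    }
    clean["marker"][:] = cfg.background
    pcna_clean = np.full((h, w), cfg.background, dtype=float)
    has_pcna = phases is not None

    m0, m1 = cfg.marker_levels
    for i, (center, ax, angle) in enumerate(placements):
        label = i + 1
        rng_cell = np.random.default_rng(cell_seeds[i])
        nuc = _jittered_ellipse_mask(
            (h, w), center, ax, angle, cfg.boundary_jitter, rng_cell
        )
        nuc &= nucleus_labels == 0  # safety; placement already avoids overlap
        ncl = _place_nucleoli(nuc, cfg, rng_cell)
        nucleus_labels[nuc] = label
        nucleolus_labels[ncl] = label
        axes[label] = ax

        f = (
            float(cfg.enrichment_per_nucleus[i])
            if cfg.enrichment_per_nucleus is not None
            else cfg.enrichment
        )
        enrichment[label] = f

        nucleoplasm = nuc & ~ncl
        clean["dapi"][nucleoplasm] = cfg.dapi_level
        clean["dapi"][ncl] = cfg.dapi_level * cfg.dapi_nucleolar_factor
        clean["marker"][nucleoplasm] = m0
        clean["marker"][ncl] = m1
        clean["query"][nucleoplasm] = cfg.query_diffuse
        clean["query"][ncl] = cfg.query_diffuse + f * cfg.query_boost

        if phases is not None:
            ph = phases[i]
            phase[label] = ph
            pat = generate_pcna_pattern(
                ph, nuc, ncl, rng=np.random.default_rng(cell_seeds[i].spawn(1)[0])
            )
            pcna_clean = np.where(nuc, pat.image, pcna_clean)
            pcna_centers[label] = pat.centers
        else:
            phase[label] = "non_S"

    if positive_control:
        clean["query"] = clean["marker"].copy()
    elif cfg.bleedthrough > 0:
        # crosstalk added on the clean signal: leaked structure, independent noise
        clean["query"] = clean["query"] + cfg.bleedthrough * clean["marker"]

    channels: dict[str, np.ndarray] = {}
    for role in ("dapi", "marker", "query"):
        channels[role] = _render_noise(
            clean[role],
            cfg.sigma_for(role),
            cfg.poisson_noise,
            cfg.bit_depth,
            rng_noise,
        )
    if has_pcna:
        channels["pcna"] = _render_noise(
            pcna_clean,
            cfg.sigma_for("pcna"),
            cfg.poisson_noise,
            cfg.bit_depth,
            rng_noise,
        )

    image = FieldImage(
        channels=channels, pixel_size=cfg.pixel_size, bit_depth=cfg.bit_depth
    )
    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        nucleolus_labels=nucleolus_labels,
        enrichment=enrichment,
        phase=phase,
        axes=axes,
        pcna_centers=pcna_centers,
        config=cfg,
    )
    return image, truth


def _resolve_phases(cfg: SimulationConfig) -> list[str] | None:
    if cfg.pcna_phases is None:
        return None
    valid = {"mid_S", "non_S"}
    if isinstance(cfg.pcna_phases, str):
        if cfg.pcna_phases not in valid:
            raise ValueError(f"unknown phase {cfg.pcna_phases!r}")
        return [cfg.pcna_phases] * cfg.n_nuclei
    phases = list(cfg.pcna_phases)
    if len(phases) != cfg.n_nuclei:
        raise ValueError("pcna_phases length must equal n_nuclei")
    if not set(phases) <= valid:
        raise ValueError("phases must be 'mid_S' or 'non_S'")
    return phases


def generate_control_field(
    config: SimulationConfig, kind: str
) -> tuple[FieldImage, GroundTruth]:
    """Field for assay calibration.

    ``kind='positive'``: query is an independent noisy rendering of the
    marker structure (same protein, two detection channels), so the
    per-cell coefficient approaches the noise-limited maximum.
    ``kind='negative'``: the standard field; the caller scores marker
    against the DAPI channel, which dips inside nucleoli, giving an
    anti-correlated pair.
    """
    if kind == "positive":
        return generate_field(config, positive_control=True)
    if kind == "negative":
        return generate_field(config)
    raise ValueError("kind must be 'positive' or 'negative'")


# --------------------------------------------------------------------------
# PCNA pattern

def generate_pcna_pattern(
    phase: str,
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    base_level: float = 120.0,
    focus_amplitude: float = 110.0,
    n_foci: int = 8,
    focus_sigma: float = 1.5,
    params: PhaseParams | None = None,
    max_tries: int = 2000,
) -> PcnaPattern:
    """Render a noiseless PCNA channel for one nucleus.

    ``non_S`` (G1/G2) cells show a spatially homogeneous nuclear signal;
    ``mid_S`` cells show ``n_foci`` bright Gaussian puncta whose centers
    lie in the peripheral ring or within a dilation of the nucleolus
    mask — the zone where replication foci cluster in mid S phase.
    Acquisition noise is added by the field renderer, not here.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    nucleolus_mask = np.asarray(nucleolus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    if rng is None:
        rng = np.random.default_rng(seed)
    params = params or PhaseParams()

    image = np.where(nucleus_mask, base_level, 0.0)
    if phase == "non_S":
        return PcnaPattern(image=image, centers=np.empty((0, 2)))
    if phase != "mid_S":
        raise ValueError(f"unknown phase {phase!r}")

    zone = zone_mask(nucleus_mask, nucleolus_mask, params)
    # keep puncta centers away from the nuclear edge so the spot stays inside
    from scipy import ndimage

    safe = zone & ndimage.binary_erosion(
        nucleus_mask, structure=np.ones((3, 3)), iterations=2
    )
    coords = np.argwhere(safe if safe.any() else zone)
    if len(coords) < n_foci:
        raise PlacementError("nucleus too small to host requested puncta")

    # prefer well-separated puncta; relax the separation in tight nuclei
    # down to a floor below which spots would merge into one blob
    min_sep = 3.0 * focus_sigma + 2.0
    sep_floor = 2.0 * focus_sigma + 1.0
    centers: list[tuple[int, int]] = []
    while len(centers) < n_foci:
        for _try in range(max_tries):
            cy, cx = coords[rng.integers(len(coords))]
            if all(math.hypot(cy - y, cx - x) >= min_sep for y, x in centers):
                centers.append((int(cy), int(cx)))
                break
        else:
            if min_sep > sep_floor:
                min_sep = max(sep_floor, 0.8 * min_sep)
                continue
            raise PlacementError("nucleus too small to host requested puncta")

    rr, cc = np.mgrid[0 : nucleus_mask.shape[0], 0 : nucleus_mask.shape[1]]
    for cy, cx in centers:
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        image += focus_amplitude * np.exp(-d2 / (2 * focus_sigma**2))
    image = np.where(nucleus_mask, image, 0.0)
    return PcnaPattern(image=image, centers=np.asarray(centers, dtype=float))


# --------------------------------------------------------------------------
# analytic oracle

def expected_pearson_two_level(
    p: float,
    dq_eff: float,
    dm: float,
    sigma_q: float,
    sigma_m: float,
) -> float:
    """Population Pearson coefficient of a noisy two-level image pair.

    Model: a fraction ``p`` of mask pixels belongs to the nucleolus;
    there the query is raised by ``dq_eff = f * dq`` and the marker by
    ``dm``; both channels carry independent additive noise of standard
    deviations ``sigma_q`` and ``sigma_m``.  The pixel-wise covariance
    is then ``p(1-p) dq_eff dm`` and each channel's variance is
    ``p(1-p) d^2 + sigma^2``, giving

        r = p(1-p) dq_eff dm
            / sqrt[(p(1-p) dq_eff^2 + sq^2)(p(1-p) dm^2 + sm^2)]

    Negative ``dq_eff`` or ``dm`` (a channel *excluded* from nucleoli,
    like DAPI) yields the anti-correlated, negative-control regime.

    Raises :class:`ZeroDivisionError` when both variance terms of either
    channel vanish (the coefficient is undefined there, exactly as the
    per-cell statistic is undefined on a constant channel).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if sigma_q < 0 or sigma_m < 0:
        raise ValueError("noise standard deviations must be non-negative")
    pq = p * (1.0 - p)
    var_q = pq * dq_eff**2 + sigma_q**2
    var_m = pq * dm**2 + sigma_m**2
    if var_q == 0.0 or var_m == 0.0:
        raise ZeroDivisionError(
            "Pearson coefficient undefined: a channel has zero variance"
        )
    return pq * dq_eff * dm / math.sqrt(var_q * var_m)
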