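"""Synthetic microscope: bead z-stacks and blinking SMLM movies.

Image formation model
---------------------
Each emitter at axial position z contributes a circular 2D Gaussian whose
standard deviation follows the Gaussian-beam defocus law

    sigma(z) = sigma0 * sqrt(1 + (z / z_r)**2)

and whose total detected photon count is held constant with defocus, so the
peak surface brightness falls as 1 / sigma(z)**2: out-of-focus emitters are
larger and dimmer, which is the physical handle the virtual light-sheet
exploits.  The expected photon image is sampled at pixel centres; noise is
Poisson shot noise (optionally scaled by an EM excess factor), then Gaussian
read noise, then baseline offset and integer quantization.

All randomness flows through a single :class:`numpy.random.Generator`, so
every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math

import numpy as np

from .models import CameraModel, FrameStack, GroundTruthEmitter, OpticsModel

__all__ = [
    "psf_sigma_at_z",
    "render_frame",
    "simulate_bead_zstack",
    "simulate_smlm_movie",
    "cluster_layout",
    "shell_layout",
]

#: how many sigmas away from an emitter centre the splatted Gaussian is cut
_RENDER_TRUNCATION_SIGMAS = 6.0


def psf_sigma_at_z(z: float | np.ndarray, optics: OpticsModel) -> float | np.ndarray:
    """PSF standard deviation (nm) of an emitter defocused by ``z`` nm.

    Even in z, equal to ``optics.sigma0`` at focus and strictly increasing
    in |z|.
    """
    z = np.asarray(z, dtype=float)
    out = optics.sigma0 * np.sqrt(1.0 + (z / optics.z_r) ** 2)
    return float(out) if out.ndim == 0 else out


def _add_gaussian_spot(
    image: np.ndarray,
    x_nm: float,
    y_nm: float,
    sigma_nm: float,
    photons: float,
    pixel_size: float,
) -> None:
    """Accumulate one emitter's expected photon image in place.

    The Gaussian is evaluated at pixel centres with peak
    ``photons / (2 pi sigma_px**2)`` so that the pixel sum approximates the
    photon count; the evaluation window is clipped to the field, silently
    truncating out-of-field tails.
    """
    h, w = image.shape
    sigma_px = sigma_nm / pixel_size
    # emitter position in pixel-centre index coordinates
    cx = x_nm / pixel_size - 0.5
    cy = y_nm / pixel_size - 0.5
    half = _RENDER_TRUNCATION_SIGMAS * sigma_px
    x_lo = max(int(math.floor(cx - half)), 0)
    x_hi = min(int(math.ceil(cx + half)) + 1, w)
    y_lo = max(int(math.floor(cy - half)), 0)
    y_hi = min(int(math.ceil(cy + half)) + 1, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = np.arange(x_lo, x_hi, dtype=float)
    ys = np.arange(y_lo, y_hi, dtype=float)
    gx = np.exp(-((xs - cx) ** 2) / (2.0 * sigma_px**2))
    gy = np.exp(-((ys - cy) ** 2) / (2.0 * sigma_px**2))
    peak = photons / (2.0 * math.pi * sigma_px**2)
    image[y_lo:y_hi, x_lo:x_hi] += peak * np.outer(gy, gx)


def render_frame(
    emitters_on: list[GroundTruthEmitter],
    shape: tuple[int, int],
    optics: OpticsModel,
    camera: CameraModel,
    background_photons_per_pixel: float = 0.0,
    rng: np.random.Generator | int | None = None,
    photons: np.ndarray | None = None,
) -> np.ndarray:
    """Render one camera frame (in counts) for the given active emitters.

    Parameters
    ----------
    emitters_on
        Emitters active in this frame; an emitter outside the field simply
        contributes whatever tail falls inside it.
    photons
        Optional per-emitter photon counts for this frame, overriding each
        emitter's ``photons`` attribute (used for per-frame brightness
        fluctuations).
    rng
        ``None`` disables all noise and quantization and returns the
        expected image in counts; a seed or Generator enables the full
        noise chain.  The same seed always yields a bit-identical frame.
    """
    if background_photons_per_pixel < 0:
        raise ValueError("background_photons_per_pixel must be >= 0")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")

    expected = np.full((h, w), float(background_photons_per_pixel))
    if photons is None:
        photons = np.array([e.photons for e in emitters_on], dtype=float)
    for emitter, n_ph in zip(emitters_on, photons):
        sigma = psf_sigma_at_z(emitter.z_nm, optics)
        _add_gaussian_spot(
            expected, emitter.x_nm, emitter.y_nm, sigma, float(n_ph), camera.pixel_size
        )

    if rng is None:
        return expected / camera.photons_per_count + camera.baseline

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = camera.em_excess_factor
    if f > 1.0:
        # EM excess noise approximated by rescaled Poisson statistics:
        # variance f * mean, as in the high-gain EMCCD limit.
        detected = f * rng.poisson(expected / f).astype(float)
    else:
        detected = rng.poisson(expected).astype(float)
    counts = detected / camera.photons_per_count + camera.baseline
    if camera.read_noise > 0:
        counts = counts + rng.normal(0.0, camera.read_noise, size=counts.shape)
    return np.clip(np.rint(counts), 0, None)


def _place_beads(
    n_beads: int,
    shape: tuple[int, int],
    pixel_size: float,
    min_separation_nm: float,
    rng: np.random.Generator,
    margin_px: float = 8.0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Random lateral positions (nm) with a minimum pairwise separation."""
    h, w = shape
    lo_x, hi_x = margin_px * pixel_size, (w - margin_px) * pixel_size
    lo_y, hi_y = margin_px * pixel_size, (h - margin_px) * pixel_size
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError(f"field {shape} too small for bead placement margin")
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < n_beads:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_beads} beads at >= {min_separation_nm:.0f} nm "
                f"separation in a {h}x{w} px field"
            )
        tries += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if all(math.hypot(x - px, y - py) >= min_separation_nm for px, py in positions):
            positions.append((x, y))
    return np.array(positions)


def simulate_bead_zstack(
    n_beads: int = 28,
    z_min: float = -1000.0,
    z_max: float = 1000.0,
    z_step: float = 10.0,
    frames_per_step: int = 10,
    photons_range: tuple[float, float] = (500.0, 1500.0),
    optics: OpticsModel | None = None,
    camera: CameraModel | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = (128, 128),
    background_photons_per_pixel: float = 2.0,
) -> FrameStack:
    """Simulate a calibration z-scan of immobile fluorescent beads.

    Beads are fixed at random lateral positions at least ``8 * sigma0``
    apart and swept axially from ``z_min`` to ``z_max`` in steps of
    ``z_step``, imaging ``frames_per_step`` frames per position (default:
    201 steps of 10 nm, 10 frames each).  Per-bead, per-frame photon
    counts are drawn uniformly from ``photons_range``.  The true z of
    every frame is recorded in ``z_per_frame`` and the bead positions in
    ``truth``.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    if z_min >= z_max:
        raise ValueError("z_min must be < z_max")
    optics = optics or OpticsModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)

    positions = _place_beads(
        n_beads, shape, camera.pixel_size, 8.0 * optics.sigma0, rng
    )
    n_steps = int(round((z_max - z_min) / z_step)) + 1
    z_steps = z_min + z_step * np.arange(n_steps)
    n_frames = n_steps * frames_per_step

    lo, hi = photons_range
    # one brightness draw per bead: a fixed bead neither blinks nor
    # bleaches, so frame-to-frame variation is shot noise only
    bead_photons = rng.uniform(lo, hi, size=n_beads)
    photon_draws = np.broadcast_to(bead_photons, (n_frames, n_beads))

    emitters = [
        GroundTruthEmitter(
            id=i,
            x_nm=positions[i, 0],
            y_nm=positions[i, 1],
            z_nm=0.0,  # replaced per frame by the stage position
            photons=float(bead_photons[i]),
        )
        for i in range(n_beads)
    ]

    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    z_per_frame = np.repeat(z_steps, frames_per_step)
    for t in range(n_frames):
        frame_emitters = [
            GroundTruthEmitter(
                id=e.id, x_nm=e.x_nm, y_nm=e.y_nm, z_nm=float(z_per_frame[t]),
                photons=e.photons,
            )
            for e in emitters
        ]
        counts = render_frame(
            frame_emitters,
            shape,
            optics,
            camera,
            background_photons_per_pixel=background_photons_per_pixel,
            rng=rng,
            photons=photon_draws[t],
        )
        frames[t] = np.clip(counts, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    return FrameStack(frames=frames, camera=camera, z_per_frame=z_per_frame, truth=emitters)


def cluster_layout(
    centers_nm: list[tuple[float, float, float]],
    n_per_cluster: int,
    cluster_sigma_nm: float,
    photons: float = 1000.0,
    seed: int | None = None,
) -> list[GroundTruthEmitter]:
    """Emitters in tight 3D clusters (one Gaussian blob per centre).

    Emulates punctate structures such as centromeric protein foci sitting
    at distinct axial positions; each cluster's members scatter laterally
    with ``cluster_sigma_nm`` and share their cluster's z.
    """
    rng = np.random.default_rng(seed)
    emitters: list[GroundTruthEmitter] = []
    eid = 0
    for cx, cy, cz in centers_nm:
        for _ in range(n_per_cluster):
            emitters.append(
                GroundTruthEmitter(
                    id=eid,
                    x_nm=float(cx + rng.normal(0, cluster_sigma_nm)),
                    y_nm=float(cy + rng.normal(0, cluster_sigma_nm)),
                    z_nm=float(cz),
                    photons=photons,
                )
            )
            eid += 1
    return emitters


def shell_layout(
    field_nm: tuple[float, float],
    n_structure: int,
    voids: list[tuple[float, float, float, float]],
    n_background: int = 0,
    background_z_range: tuple[float, float] = (400.0, 800.0),
    photons: float = 1000.0,
    seed: int | None = None,
) -> list[GroundTruthEmitter]:
    """In-focus labelled structure perforated by elliptical voids, plus an
    out-of-focus haze.

    ``n_structure`` emitters are placed uniformly at z = 0 but excluded
    from the ``voids`` (each ``(cx, cy, rx, ry)`` in nm) — emulating, e.g.,
    a membrane stain around unlabelled vacuoles.  ``n_background`` emitters
    are placed uniformly everywhere (voids included) at defocused |z| drawn
    from ``background_z_range`` with random sign, providing the haze that
    axial filtering should remove.
    """
    rng = np.random.default_rng(seed)
    wx, wy = field_nm

    def in_void(x: float, y: float) -> bool:
        return any(
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
            for cx, cy, rx, ry in voids
        )

    emitters: list[GroundTruthEmitter] = []
    eid = 0
    while sum(1 for e in emitters if e.z_nm == 0.0) < n_structure:
        x, y = rng.uniform(0, wx), rng.uniform(0, wy)
        if in_void(x, y):
            continue
        emitters.append(GroundTruthEmitter(eid, float(x), float(y), 0.0, photons))
        eid += 1
    z_lo, z_hi = background_z_range
    for _ in range(n_background):
        x, y = rng.uniform(0, wx), rng.uniform(0, wy)
        z = rng.uniform(z_lo, z_hi) * rng.choice([-1.0, 1.0])
        emitters.append(GroundTruthEmitter(eid, float(x), float(y), float(z), photons))
        eid += 1
    return emitters


def simulate_smlm_movie(
    emitter_layout: list[GroundTruthEmitter],
    n_frames: int,
    mean_on_frames: float = 3.0,
    photons_range: tuple[float, float] = (500.0, 1500.0),
    optics: OpticsModel | None = None,
    camera: CameraModel | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = (64, 64),
    background_photons_per_pixel: float = 2.0,
    max_on_per_frame: int = 30,
) -> FrameStack:
    """Simulate a blinking SMLM acquisition of a fixed emitter layout.

    Each emitter photo-activates at most once, at a random frame, and then
    stays on for a geometrically distributed burst with mean
    ``mean_on_frames`` before bleaching.  At most ``max_on_per_frame``
    emitters are simultaneously active (further activations are deferred).
    The returned truth records each emitter's ``on_frames`` and its fixed z.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mean_on_frames < 1:
        raise ValueError("mean_on_frames must be >= 1")
    optics = optics or OpticsModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)

    n = len(emitter_layout)
    # every emitter photo-activates exactly once, at a random frame;
    # activations beyond the density cap are deferred to later frames
    activation_frame = rng.integers(0, n_frames, size=n)
    burst_lengths = rng.geometric(1.0 / mean_on_frames, size=n)
    schedule: dict[int, list[int]] = {}
    for i in np.argsort(activation_frame, kind="stable"):
        schedule.setdefault(int(activation_frame[i]), []).append(int(i))

    deferred: list[int] = []
    active: list[tuple[int, int]] = []  # (emitter index, frames remaining)
    on_frames: dict[int, list[int]] = {i: [] for i in range(n)}

    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    lo, hi = photons_range
    for t in range(n_frames):
        deferred.extend(schedule.get(t, []))
        while deferred and len(active) < max_on_per_frame:
            idx = deferred.pop(0)
            active.append((idx, int(burst_lengths[idx])))
        emitters_on = [emitter_layout[i] for i, _ in active]
        photon_draws = rng.uniform(lo, hi, size=len(active))
        for i, _ in active:
            on_frames[i].append(t)
        counts = render_frame(
            emitters_on,
            shape,
            optics,
            camera,
            background_photons_per_pixel=background_photons_per_pixel,
            rng=rng,
            photons=photon_draws,
        )
        frames[t] = np.clip(counts, 0, np.iinfo(np.uint16).max).astype(np.uint16)
        active = [(i, k - 1) for i, k in active if k - 1 > 0]

    truth = [
        GroundTruthEmitter(
            id=e.id,
            x_nm=e.x_nm,
            y_nm=e.y_nm,
            z_nm=e.z_nm,
            photons=e.photons,
            on_frames=frozenset(on_frames[i]),
        )
        for i, e in enumerate(emitter_layout)
    ]
    return FrameStack(frames=frames, camera=camera, z_per_frame=None, truth=truth)
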