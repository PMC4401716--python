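"""Core data containers shared by the simulator, the fitter and the calibration.

Conventions used throughout the package:

* lateral coordinates (x, y) are continuous and expressed in nanometres;
  pixel (0, 0) spans ``[0, pixel_size)`` in each direction, i.e. pixels are
  0-based and half-open, and the centre of pixel ``i`` sits at
  ``(i + 0.5) * pixel_size``;
* the axial coordinate z is measured in nanometres relative to the focal
  plane (z = 0 in focus); the sign is conventional — the symmetric defocus
  model makes it unobservable;
* raw images are stored in camera counts (ADU); photon conversion goes
  through :class:`CameraModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsModel",
    "CameraModel",
    "GroundTruthEmitter",
    "FrameStack",
]


@dataclass(frozen=True)
class OpticsModel:
    """Geometric-optics description of the point-spread function.

    Parameters
    ----------
    sigma0
        In-focus PSF standard deviation in nm.  The default, 175 nm,
        matches the width of a typical high-NA oil objective imaging
        505-nm-emitting beads.
    z_r
        Defocus depth scale in nm: the distance over which the PSF width
        grows by a factor of sqrt(2) (Gaussian-beam form).
    wavelength_tag
        Free-form label for bookkeeping; not used in any computation.
    """

    sigma0: float = 175.0
    z_r: float = 400.0
    wavelength_tag: str = "505nm"

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if not self.z_r > 0:
            raise ValueError(f"z_r must be > 0, got {self.z_r}")


@dataclass(frozen=True)
class CameraModel:
    """Camera geometry and noise parameters.

    Parameters
    ----------
    pixel_size
        Back-projected pixel size in nm.
    photons_per_count
        Conversion gain in photons per ADU; 1.0 means images are already
        in photon units.
    read_noise
        Gaussian readout noise, rms, in counts.
    baseline
        Constant camera offset in counts.
    em_excess_factor
        Multiplicative variance excess of an electron-multiplying
        register (2 for an EMCCD in the high-gain limit, 1 for none).
    """

    pixel_size: float = 100.0
    photons_per_count: float = 1.0
    read_noise: float = 1.0
    baseline: float = 100.0
    em_excess_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.photons_per_count > 0:
            raise ValueError(
                f"photons_per_count must be > 0, got {self.photons_per_count}"
            )
        if self.read_noise < 0:
            raise ValueError(f"read_noise must be >= 0, got {self.read_noise}")
        if self.em_excess_factor < 1:
            raise ValueError(
                f"em_excess_factor must be >= 1, got {self.em_excess_factor}"
            )

    @property
    def pixel_area_um2(self) -> float:
        """Pixel area in square micrometres."""
        return (self.pixel_size * 1e-3) ** 2

    def counts_to_photons(self, frame: np.ndarray) -> np.ndarray:
        """Convert a raw frame in counts to photons (baseline removed)."""
        return (np.asarray(frame, dtype=float) - self.baseline) * self.photons_per_count


@dataclass
class GroundTruthEmitter:
    """A simulated point emitter with known position and brightness.

    ``photons`` is the expected number of detected photons per on-frame;
    ``on_frames`` lists the frames in which a blinking emitter is active
    (``None`` for always-on calibration beads).
    """

    id: int
    x_nm: float
    y_nm: float
    z_nm: float
    photons: float
    on_frames: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not self.photons > 0:
            raise ValueError(f"photons must be > 0, got {self.photons}")


@dataclass
class FrameStack:
    """A stack of camera frames with optional per-frame z and ground truth.

    ``frames`` is an ``(n_frames, h, w)`` array in camera counts.  For
    calibration z-stacks ``z_per_frame`` records the stage position of
    every frame; simulated stacks additionally carry their ground-truth
    emitter list in ``truth``.
    """

    frames: np.ndarray
    camera: CameraModel = field(default_factory=CameraModel)
    z_per_frame: np.ndarray | None = None
    truth: list[GroundTruthEmitter] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, h, w) array, got shape {self.frames.shape}"
            )
        if self.z_per_frame is not None:
            self.z_per_frame = np.asarray(self.z_per_frame, dtype=float)
            if len(self.z_per_frame) != len(self.frames):
                raise ValueError(
                    f"z_per_frame has {len(self.z_per_frame)} entries for "
                    f"{len(self.frames)} frames"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def photons(self, index: int) -> np.ndarray:
        """Frame ``index`` converted to photon units."""
        return self.camera.counts_to_photons(self.frames[index])
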