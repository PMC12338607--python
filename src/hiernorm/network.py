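"""Ring geometry, orientation tuning, and connectivity for normalization circuits.

Principal neurons in each modeled cortical area are arranged on a ring
representing preferred stimulus orientation (180-degree periodic).  All
connectivity matrices are circulant functions of circular orientation
distance: a raised-cosine encoding matrix (tuning curves), a
center-surround recurrent matrix rescaled to unit spectral radius, and a
nonnegative, symmetric, diagonally dominant inter-areal matrix whose
transpose serves as the matching feedforward projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import circulant

__all__ = [
    "RingGeometry",
    "Stimulus",
    "Connectivity",
    "circular_distance",
    "build_tuning_curves",
    "build_recurrent_weights",
    "build_feedback_weights",
    "normalization_matrix",
    "input_drive",
]

#: Period of the orientation domain in degrees (orientation, not direction).
ORIENTATION_PERIOD = 180.0


class ConnectivityError(ValueError):
    """Raised when a kernel parameterization cannot produce a valid matrix."""


@dataclass(frozen=True)
class RingGeometry:
    """Ring of orientation-tuned neurons shared by all four cell types.

    Parameters
    ----------
    n_neurons
        Number of neurons per cell type per area (>= 4).  Preferred
        orientations are equally spaced on [0, 180) degrees.
    """

    n_neurons: int = 72

    def __post_init__(self) -> None:
        if self.n_neurons < 4:
            raise ValueError(f"n_neurons must be >= 4, got {self.n_neurons}")

    @property
    def preferred_orientations(self) -> np.ndarray:
        """Preferred orientations in degrees, strictly increasing on [0, 180)."""
        n = self.n_neurons
        return np.arange(n) * (ORIENTATION_PERIOD / n)

    @property
    def spacing(self) -> float:
        return ORIENTATION_PERIOD / self.n_neurons


@dataclass(frozen=True)
class Stimulus:
    """Oriented grating described by contrast (%) and orientation (deg)."""

    contrast: float  # percent, in [0, 100]
    orientation: float = 0.0  # degrees; reduced mod 180

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError(f"contrast must be >= 0, got {self.contrast}")
        object.__setattr__(
            self, "orientation", float(self.orientation) % ORIENTATION_PERIOD
        )

    @property
    def amplitude(self) -> float:
        """Drive amplitude in [0, 1] (contrast is stored as percent)."""
        return self.contrast / 100.0


def circular_distance(theta_a, theta_b) -> np.ndarray:
    """Wrap-around orientation distance in degrees, in [0, 90]."""
    d = np.abs(np.asarray(theta_a, dtype=float) - np.asarray(theta_b, dtype=float))
    d = d % ORIENTATION_PERIOD
    return np.minimum(d, ORIENTATION_PERIOD - d)


def _circulant_from_kernel(first_row: np.ndarray) -> np.ndarray:
    # circulant(c) has first *column* c; for a symmetric kernel the result
    # is the same either way, but keep row semantics explicit.
    return circulant(first_row).T


def build_tuning_curves(geometry: RingGeometry, half_width: float = 40.0) -> np.ndarray:
    """Raised-cosine orientation tuning curves as an encoding matrix.

    Row ``i`` is the tuning curve of neuron ``i``: ``cos^2(pi*d/(2*half_width))``
    for circular distance ``d < half_width`` from the preferred orientation and
    zero outside the support.  Rows are circular shifts of one another and peak
    at exactly 1.

    Parameters
    ----------
    geometry
        Ring geometry defining the preferred orientations (columns sample the
        same orientation grid).
    half_width
        Half width of the raised-cosine support in degrees, in (0, 90).
    """
    if not (0.0 < half_width < 90.0):
        raise ValueError(f"half_width must lie in (0, 90) degrees, got {half_width}")
    theta = geometry.preferred_orientations
    d = circular_distance(theta[0], theta)
    row = np.where(
        d < half_width, np.cos(np.pi * d / (2.0 * half_width)) ** 2, 0.0
    )
    # enforce exact zero at the support boundary against roundoff
    row[d >= half_width] = 0.0
    return _circulant_from_kernel(row)


def tuning_curve_value(
    orientation: float, preferred: np.ndarray, half_width: float = 40.0
) -> np.ndarray:
    """Evaluate each neuron's raised-cosine tuning curve at one orientation."""
    d = circular_distance(orientation, preferred)
    return np.where(d < half_width, np.cos(np.pi * d / (2.0 * half_width)) ** 2, 0.0)


def _circular_gaussian(d: np.ndarray, width: float) -> np.ndarray:
    return np.exp(-0.5 * (d / width) ** 2)


def build_recurrent_weights(
    geometry: RingGeometry,
    excit_width: float = 45.0,
    inhib_width: float = 90.0,
    inhib_strength: float = 0.5,
) -> np.ndarray:
    """Center-surround recurrent matrix with unit spectral radius.

    The kernel is a difference of circular Gaussians,
    ``exp(-d^2/2σ_E^2) - inhib_strength * exp(-d^2/2σ_I^2)``, so that nearby
    connections are excitatory and distant ones inhibitory.  The resulting
    circulant matrix is rescaled so its largest-magnitude eigenvalue is
    exactly 1.

    Raises
    ------
    ConnectivityError
        If the parameters leave no positive self-connection (all-nonpositive
        kernel), which cannot be rescaled into an amplifying recurrence.
    """
    if not (0.0 < excit_width < inhib_width):
        raise ValueError(
            f"need 0 < excit_width < inhib_width, got {excit_width}, {inhib_width}"
        )
    if inhib_strength < 0:
        raise ValueError(f"inhib_strength must be >= 0, got {inhib_strength}")
    theta = geometry.preferred_orientations
    d = circular_distance(theta[0], theta)
    kernel = _circular_gaussian(d, excit_width) - inhib_strength * _circular_gaussian(
        d, inhib_width
    )
    if kernel[0] <= 0.0:
        raise ConnectivityError(
            "recurrent kernel is non-positive at zero distance; "
            "reduce inhib_strength or widen the excitatory lobe"
        )
    w = _circulant_from_kernel(kernel)
    # circulant spectral radius == max |DFT(first row)|
    radius = np.max(np.abs(np.fft.fft(kernel)))
    return w / radius


def build_feedback_weights(
    geometry: RingGeometry,
    width: float = 15.0,
    diag_boost: float = 2.0,
    row_sum: float = 0.75,
) -> np.ndarray:
    """Nonnegative, symmetric, diagonally dominant inter-areal matrix.

    A circular Gaussian kernel of the given width is given a self-connection
    equal to ``diag_boost`` times the summed off-diagonal weight of the row
    (row-wise diagonal dominance for any ``diag_boost > 1``), then every row
    is rescaled to sum to ``row_sum``.  The matrix is circulant and symmetric,
    so the feedforward projection (its transpose) is identical to it.

    Raises
    ------
    ConnectivityError
        If the construction fails row-wise diagonal dominance (only possible
        for ``diag_boost <= 1``); the failing row index is reported.
    """
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    if diag_boost < 1:
        raise ValueError(f"diag_boost must be >= 1, got {diag_boost}")
    theta = geometry.preferred_orientations
    d = circular_distance(theta[0], theta)
    kernel = _circular_gaussian(d, width)
    kernel[0] = 0.0
    off_sum = kernel.sum()
    kernel[0] = diag_boost * off_sum
    kernel *= row_sum / kernel.sum()
    w = _circulant_from_kernel(kernel)
    w = 0.5 * (w + w.T)  # circulant symmetric kernel already; cancel roundoff
    slack = 2 * np.diag(w) - w.sum(axis=1)
    bad = np.flatnonzero(slack <= 0)
    if bad.size:
        raise ConnectivityError(
            f"feedback matrix is not diagonally dominant in row {bad[0]}"
        )
    return w


def normalization_matrix(geometry: RingGeometry) -> np.ndarray:
    """Uniform normalization pool: every neuron contributes equally.

    Scaled by ``1/n_neurons`` so the pool is the population average, which
    keeps the semisaturation contrast ``sigma / sqrt(mean tuning^2)`` in the
    physiological range for the default Table parameters.
    """
    n = geometry.n_neurons
    return np.full((n, n), 1.0 / n)


def input_drive(
    stimulus: Stimulus, geometry: RingGeometry, half_width: float = 40.0
) -> np.ndarray:
    """Input drive to the principal neurons of the bottom area.

    The upstream relay stage is collapsed: the drive is the stimulus contrast
    (as a [0, 1] amplitude) times each neuron's tuning-curve value at the
    stimulus orientation.
    """
    tc = tuning_curve_value(
        stimulus.orientation, geometry.preferred_orientations, half_width
    )
    return stimulus.amplitude * tc


@dataclass
class Connectivity:
    """All weight matrices of a two-area (or per-edge) circuit.

    Attributes follow the field's naming: ``W_zx`` encodes tuning curves,
    ``W_11``/``W_22`` are recurrent matrices, ``W_12`` is the feedback matrix
    (area 1 <- area 2), and the feedforward matrix ``W_21`` is its transpose
    (identical, since ``W_12`` is symmetric).  ``N_1``/``N_2`` are the uniform
    normalization pools.
    """

    W_zx: np.ndarray
    W_11: np.ndarray
    W_22: np.ndarray
    W_12: np.ndarray
    N_1: np.ndarray
    N_2: np.ndarray

    @property
    def W_21(self) -> np.ndarray:
        return self.W_12.T

    @classmethod
    def default(
        cls,
        geometry: RingGeometry | None = None,
        tuning_half_width: float = 40.0,
        excit_width: float = 45.0,
        inhib_width: float = 90.0,
        inhib_strength: float = 0.5,
        feedback_width: float = 15.0,
        diag_boost: float = 2.0,
        feedback_row_sum: float = 0.75,
    ) -> "Connectivity":
        geometry = geometry or RingGeometry()
        w_rec = build_recurrent_weights(
            geometry, excit_width, inhib_width, inhib_strength
        )
        return cls(
            W_zx=build_tuning_curves(geometry, tuning_half_width),
            W_11=w_rec,
            W_22=w_rec.copy(),
            W_12=build_feedback_weights(
                geometry, feedback_width, diag_boost, feedback_row_sum
            ),
            N_1=normalization_matrix(geometry),
            N_2=normalization_matrix(geometry),
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("W_zx", "W_11", "W_22", "W_12", "N_1", "N_2"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("W_21", data=self.W_21)

    def to_csv(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("W_zx", "W_11", "W_22", "W_12", "N_1", "N_2"):
            np.savetxt(directory / f"{name}.csv", getattr(self, name), delimiter=",")
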