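"""Periodic square simulation domain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft


@dataclass(frozen=True)
class Domain:
    """Periodic square domain [-L, L) x [-L, L) with N x N grid points.

    The grid excludes the +L edge (it is identified with -L). All distances
    on the domain are minimum-image distances, consistent with the periodic
    convolutions used by the simulator.

    Parameters
    ----------
    L : float
        Half-width of the square in model units.
    N : int
        Number of grid points per side (a power of two is recommended for
        the FFTs).
    """

    L: float = 30.0
    N: int = 128

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.N < 4:
            raise ValueError("N must be at least 4")

    @property
    def h(self) -> float:
        """Grid spacing."""
        return 2.0 * self.L / self.N

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    @property
    def coords(self) -> np.ndarray:
        """1D grid coordinates in [-L, L)."""
        return -self.L + self.h * np.arange(self.N)

    def wrap(self, dx: np.ndarray | float) -> np.ndarray:
        """Minimum-image displacement(s) on the periodic axis."""
        return (np.asarray(dx) + self.L) % (2.0 * self.L) - self.L

    def radius_from(self, center: tuple[float, float]) -> np.ndarray:
        """Minimum-image radial distance of every grid node from ``center``.

        Returns an (N, N) array indexed [iy, ix].
        """
        x = self.coords
        dx = self.wrap(x - center[0])
        dy = self.wrap(x - center[1])
        return np.hypot(dx[None, :], dy[:, None])

    @property
    def radius_origin(self) -> np.ndarray:
        """Minimum-image distance of each node from the node at index (0, 0).

        This is the sampling grid for convolution kernels, whose origin sits
        at array index (0, 0) as required by the FFT convention.
        """
        d = self.wrap(self.h * np.arange(self.N))
        return np.hypot(d[None, :], d[:, None])

    @property
    def k_radial(self) -> np.ndarray:
        """Minimum-image radial wavenumber |k| for the full FFT grid."""
        k = 2.0 * np.pi * sfft.fftfreq(self.N, d=self.h)
        return np.hypot(k[None, :], k[:, None])

    def nearest_node(self, point: tuple[float, float]) -> tuple[int, int]:
        """Grid index (iy, ix) of the node nearest to ``point``."""
        x = self.coords
        ix = int(np.argmin(np.abs(self.wrap(x - point[0]))))
        iy = int(np.argmin(np.abs(self.wrap(x - point[1]))))
        return iy, ix

    def node_xy(self, index: tuple[int, int]) -> tuple[float, float]:
        """(x, y) coordinates of the node at array index (iy, ix)."""
        x = self.coords
        return float(x[index[1]]), float(x[index[0]])
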