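"""Four-electrode measurement schemes and geometric factors.

A surface survey injects current through an electrode pair (A, B) and records
the potential difference over a pair (M, N); the transfer impedance is
``Z = U_MN / I_AB``.  On a homogeneous half-space with point electrodes at the
surface, ``Z = rho / K`` with the geometric factor

    K = 2*pi / (1/r_AM - 1/r_AN - 1/r_BM + 1/r_BN).

Scheme enumeration follows common field practice for multi-channel impedance
tomographs: for every injection dipole all remaining potential dipoles are
formed, configurations with large |K| (poor signal-to-noise) are discarded,
and dipoles re-using the electrodes that carried current in the immediately
preceding injection are dropped to avoid residual electrode polarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeArray",
    "FourPointConfig",
    "MeasurementScheme",
    "geometric_factor",
    "superpose_three_point",
    "enumerate_scheme",
]


@dataclass(frozen=True)
class ElectrodeArray:
    """Surface electrode positions (x, z) in metres; indices are 1-based."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2): x and z in metres")
        if pos.shape[0] < 4:
            raise ValueError("need at least 4 electrodes")
        # pairwise-distinct positions
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d == 0):
            raise ValueError("electrode positions must be distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def coords(self, idx: int) -> np.ndarray:
        """Position of 1-based electrode index ``idx``."""
        if not 1 <= idx <= self.n:
            raise IndexError(f"electrode index {idx} out of range 1..{self.n}")
        return self.positions[idx - 1]

    @classmethod
    def line(cls, n: int, spacing: float) -> "ElectrodeArray":
        x = np.arange(n) * spacing
        return cls(np.column_stack([x, np.zeros(n)]))


@dataclass(frozen=True)
class FourPointConfig:
    a: int
    b: int
    m: int
    n: int
    k: float  # geometric factor in m

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.m, self.n}) != 4:
            raise ValueError("A, B, M, N must be four distinct electrodes")
        if not np.isfinite(self.k) or self.k == 0:
            raise ValueError("geometric factor must be finite and nonzero")

    @property
    def abmn(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.m, self.n)


@dataclass
class MeasurementScheme:
    array: ElectrodeArray
    injections: list[tuple[int, int]]
    configs: list[FourPointConfig] = field(repr=False)

    def __post_init__(self) -> None:
        inj = set(self.injections)
        seen: set[tuple[int, int, int, int]] = set()
        for c in self.configs:
            if (c.a, c.b) not in inj:
                raise ValueError(f"config {c.abmn} has unknown injection ({c.a},{c.b})")
            if c.abmn in seen:
                raise ValueError(f"duplicate configuration {c.abmn}")
            seen.add(c.abmn)

    def __len__(self) -> int:
        return len(self.configs)


def _inv_dist(array: ElectrodeArray, i: int, j: int) -> float:
    r = float(np.linalg.norm(array.coords(i) - array.coords(j)))
    if r == 0:
        raise ValueError(f"electrodes {i} and {j} coincide")
    return 1.0 / r


def geometric_factor(array: ElectrodeArray, a: int, b: int, m: int, n: int) -> float:
    """Half-space geometric factor K in m for surface point electrodes.

    Satisfies ``Z = rho / K`` over a homogeneous half-space of resistivity rho.
    The sign of K carries the dipole orientation.
    """
    denom = (
        _inv_dist(array, a, m)
        - _inv_dist(array, a, n)
        - _inv_dist(array, b, m)
        + _inv_dist(array, b, n)
    )
    if denom == 0:
        raise ValueError(
            f"degenerate geometry for (A,B,M,N)=({a},{b},{m},{n}): "
            "geometric-factor denominator is zero"
        )
    return 2.0 * np.pi / denom


def superpose_three_point(u_m: complex, u_n: complex, current: complex) -> complex:
    """Four-point transfer impedance from two three-point potentials.

    Multi-channel tomographs record every electrode's potential against one
    reference per injection; any four-point impedance follows by superposition:
    ``Z = (U_M - U_N) / I``.
    """
    if current == 0:
        raise ValueError("injected current must be nonzero")
    return (complex(u_m) - complex(u_n)) / complex(current)


def enumerate_scheme(
    array: ElectrodeArray,
    injections: list[tuple[int, int]],
    max_abs_k: float = 5.0,
    exclude_previous_injection: bool = True,
) -> MeasurementScheme:
    """Build the full measurement scheme for an ordered injection list.

    For each injection (A, B), every unordered potential dipole {M, N} disjoint
    from {A, B} is formed (stored with M < N; the sign of K carries
    orientation).  Configurations with |K| > ``max_abs_k`` are dropped.  If
    ``exclude_previous_injection`` is set, dipoles of injection i that re-use
    an electrode that was A or B of injection i-1 are dropped.  Ordering is
    deterministic: injection order, then M, then N ascending.
    """
    configs: list[FourPointConfig] = []
    prev: set[int] = set()
    for a, b in injections:
        if a == b:
            raise ValueError(f"injection electrodes coincide: ({a},{b})")
        others = [e for e in range(1, array.n + 1) if e not in (a, b)]
        for i, m in enumerate(others):
            for n in others[i + 1 :]:
                if exclude_previous_injection and (m in prev or n in prev):
                    continue
                try:
                    k = geometric_factor(array, a, b, m, n)
                except ValueError:
                    # zero-denominator dipole: infinite |K|, never acquirable
                    continue
                if abs(k) > max_abs_k:
                    continue
                configs.append(FourPointConfig(a, b, m, n, k))
        prev = {a, b}
    if not configs:
        warnings.warn("scheme enumeration produced no configurations", stacklevel=2)
    return MeasurementScheme(array, list(injections), configs)
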