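"""Ring-lattice larval dispersal network with optional nursery patches.

Reef patches are arranged on a ring in order of their thermal rank (the
hottest and coldest ends are joined), and each patch exchanges larvae with
itself and its four nearest neighbours in temperature rank — two on each
side — all with equal arrival probability.  Restoration is represented by
auxiliary *nursery* patches: each nursery exports larvae to exactly one
target reef (arrival probability 1) and receives nothing; its cover and
trait are imposed externally rather than simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReefNetwork",
    "build_ring_lattice",
    "attach_nurseries",
    "larval_input",
    "immigrant_trait",
]


@dataclass(frozen=True)
class ReefNetwork:
    """Dispersal topology over reef patches plus any attached nurseries.

    ``D[a, b]`` is the probability that larvae produced at patch ``b`` arrive
    at patch ``a``.  The first ``n_reefs`` rows/columns are reef patches (in
    thermal rank order, coldest first); any further ones are nurseries.
    Nursery rows are zero (their state is imposed, not dynamical).
    """

    n_reefs: int
    D: np.ndarray
    nursery_targets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n_tot = self.n_reefs + self.n_nurseries
        if self.D.shape != (n_tot, n_tot):
            raise ValueError(
                f"connectivity matrix shape {self.D.shape} does not match "
                f"{n_tot} patches"
            )
        if np.any(self.D < 0) or np.any(self.D > 1):
            raise ValueError("connectivity entries must be probabilities in [0, 1]")
        self.D.setflags(write=False)

    @property
    def n_nurseries(self) -> int:
        return len(self.nursery_targets)

    @property
    def n_patches(self) -> int:
        return self.n_reefs + self.n_nurseries

    @property
    def reef_rows(self) -> np.ndarray:
        """Rows of D for reef patches (their larval arrival weights)."""
        return self.D[: self.n_reefs, :]

    @property
    def nursery_of(self) -> dict[int, int]:
        """Mapping target reef index -> nursery patch index (into D)."""
        return {t: self.n_reefs + i for i, t in enumerate(self.nursery_targets)}


def _ring_positions(n_reefs: int, layout: str) -> np.ndarray:
    """Ring position of each thermal rank.

    ``folded`` (default) places ranks around the ring so temperature is
    unimodal: even ranks ascend one arm, odd ranks descend the other, putting
    the hottest patches together on one side of the ring and the coldest on
    the opposite side with no hot-cold discontinuity anywhere.  ``rank``
    places ranks monotonically, which joins the hottest directly to the
    coldest at the wraparound.
    """
    if layout == "rank":
        return np.arange(n_reefs)
    if layout == "folded":
        pos = np.empty(n_reefs, dtype=int)
        for r in range(n_reefs):
            pos[r] = r // 2 if r % 2 == 0 else n_reefs - (r + 1) // 2
        return pos
    raise ValueError(f"unknown ring layout {layout!r}")


def build_ring_lattice(
    n_reefs: int = 20,
    k_neighbors: int = 4,
    weight: float = 0.2,
    layout: str = "folded",
) -> ReefNetwork:
    """Build the ring lattice: self-loop plus ``k_neighbors`` nearest neighbours.

    Patches are indexed by thermal rank (coldest first) and arranged on a
    ring; each exchanges larvae with itself and the ``k/2`` patches on each
    side of its ring position, all with equal ``weight``.  The default
    ``folded`` layout makes every patch's neighbours its thermally most
    similar ones (hottest patches cluster on one side of the ring); the
    ``rank`` layout instead orders the ring monotonically in temperature,
    joining the thermal extremes at the wraparound.
    """
    if k_neighbors % 2 != 0:
        raise ValueError(f"k_neighbors must be even, got {k_neighbors}")
    if k_neighbors >= n_reefs:
        raise ValueError(
            f"k_neighbors ({k_neighbors}) must be smaller than n_reefs ({n_reefs})"
        )
    pos = _ring_positions(n_reefs, layout)
    rank_at = np.empty(n_reefs, dtype=int)
    rank_at[pos] = np.arange(n_reefs)
    D = np.zeros((n_reefs, n_reefs))
    half = k_neighbors // 2
    for a in range(n_reefs):
        D[a, a] = weight
        for off in range(1, half + 1):
            D[a, rank_at[(pos[a] - off) % n_reefs]] = weight
            D[a, rank_at[(pos[a] + off) % n_reefs]] = weight
    return ReefNetwork(n_reefs=n_reefs, D=D)


def attach_nurseries(net: ReefNetwork, targets) -> ReefNetwork:
    """Attach one nursery per target reef; each exports to its target with D = 1."""
    targets = tuple(int(t) for t in targets)
    if len(set(targets)) != len(targets):
        raise ValueError(f"duplicate nursery targets: {targets}")
    if any(t < 0 or t >= net.n_reefs for t in targets):
        raise ValueError(f"nursery targets out of range: {targets}")
    if net.n_nurseries:
        raise ValueError("network already has nurseries attached")
    if not targets:
        return net
    n, k = net.n_reefs, len(targets)
    D = np.zeros((n + k, n + k))
    D[:n, :n] = net.D
    for i, t in enumerate(targets):
        D[t, n + i] = 1.0
    return ReefNetwork(n_reefs=n, D=D, nursery_targets=targets)


def larval_input(net: ReefNetwork, C: np.ndarray, beta: float) -> np.ndarray:
    """Per-reef larval input rate ``l_a = beta * sum_b D_ab C_b`` (1/yr).

    ``C`` must cover all patches including nurseries (at their imposed
    covers); the result has one entry per reef patch.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (net.n_patches,):
        raise ValueError(
            f"cover vector length {C.shape} does not match {net.n_patches} patches"
        )
    return beta * (net.reef_rows @ C)


def immigrant_trait(
    net: ReefNetwork,
    C: np.ndarray,
    z: np.ndarray,
    beta: float,
    l: np.ndarray | None = None,
) -> np.ndarray:
    """Cover-weighted mean thermal optimum of larvae arriving at each reef.

    ``z_i,a = beta * sum_b D_ab C_b z_b / l_a``.  Where ``l_a == 0`` (no
    immigrants) the resident trait ``z_a`` is returned, so gene flow exerts
    no forcing.
    """
    C = np.asarray(C, dtype=float)
    z = np.asarray(z, dtype=float)
    if C.shape != (net.n_patches,) or z.shape != (net.n_patches,):
        raise ValueError("cover and trait vectors must cover all patches")
    if l is None:
        l = larval_input(net, C, beta)
    num = beta * (net.reef_rows @ (C * z))
    resident = z[: net.n_reefs]
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = np.where(l > 0, num / np.where(l > 0, l, 1.0), resident)
    return zi
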