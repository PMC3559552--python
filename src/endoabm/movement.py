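"""Random-walk movement, interaction attraction and import draws.

All functions are vectorized over numpy arrays; a single molecule is the
length-1 special case.  The walk is a persistent Moore-neighbourhood walk:
an agent waits ``w ~ U{0..max_wait}`` ticks, then takes one lattice step per
tick in a fixed direction for ``n ~ U{1..max_persist}`` steps before
redrawing direction, persistence and wait.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "MOORE_OFFSETS", "draw_directions", "redraw_walk", "advance_walk",
    "step_walk", "apply_attraction", "attraction_field", "import_mask",
]

# the 8 Moore directions, ordered N, NE, E, SE, S, SW, W, NW
MOORE_OFFSETS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)],
    dtype=np.int8)


def draw_directions(n: int, rng: np.random.Generator):
    """Draw ``n`` directions uniformly from the 8 Moore directions."""
    d = rng.integers(0, 8, n)
    off = MOORE_OFFSETS[d]
    return off[:, 0].copy(), off[:, 1].copy()


def redraw_walk(idx_or_mask, dirx, diry, steps, wait, rng,
                max_persist: int = 5, max_wait: int = 2) -> None:
    """Redraw direction, persistence and wait for the selected agents (in place)."""
    k = int(np.count_nonzero(idx_or_mask)) if idx_or_mask.dtype == bool \
        else len(idx_or_mask)
    if k == 0:
        return
    dx, dy = draw_directions(k, rng)
    dirx[idx_or_mask] = dx
    diry[idx_or_mask] = dy
    steps[idx_or_mask] = rng.integers(1, max_persist + 1, k)
    wait[idx_or_mask] = rng.integers(0, max_wait + 1, k)


def advance_walk(x, y, dirx, diry, steps, wait, mobile, rng,
                 max_persist: int = 5, max_wait: int = 2):
    """One tick of the random walk for every agent (state updated in place).

    Waiting agents decrement ``wait`` and stay put.  Moving agents propose a
    one-step displacement along their heading and decrement ``steps``;
    exhausted agents redraw direction/persistence/wait.  Returns
    ``(px, py, moved)``: proposed positions (unconstrained -- the caller
    applies compartment rules before committing) and the mask of agents that
    attempted a move.
    """
    waiting = mobile & (wait > 0)
    wait[waiting] -= 1
    moved = mobile & ~waiting
    px = x + np.where(moved, dirx, 0).astype(x.dtype)
    py = y + np.where(moved, diry, 0).astype(y.dtype)
    steps[moved] -= 1
    exhausted = moved & (steps <= 0)
    redraw_walk(exhausted, dirx, diry, steps, wait, rng, max_persist, max_wait)
    return px, py, moved


def step_walk(pos, walk, grid_shape, rng, max_persist: int = 5, max_wait: int = 2):
    """Single-agent walk step on a bounded grid (positions clamped).

    ``pos = (x, y)``; ``walk = dict(dirx, diry, steps, wait)`` mutated in
    place.  Returns the new position.  Convenience wrapper over
    :func:`advance_walk` for scalar use.
    """
    x = np.array([pos[0]], dtype=np.int16)
    y = np.array([pos[1]], dtype=np.int16)
    arrs = {k: np.array([walk[k]], dtype=np.int16) for k in
            ("dirx", "diry", "steps", "wait")}
    px, py, moved = advance_walk(
        x, y, arrs["dirx"], arrs["diry"], arrs["steps"], arrs["wait"],
        np.array([True]), rng, max_persist, max_wait)
    nx = int(np.clip(px[0], 0, grid_shape[0] - 1))
    ny = int(np.clip(py[0], 0, grid_shape[1] - 1))
    for k in arrs:
        walk[k] = int(arrs[k][0])
    return nx, ny


def apply_attraction(ax, ay, bx, by, theta: int):
    """Headings for an interactive pair within the attraction threshold.

    If the Chebyshev distance between ``a`` and ``b`` is strictly below
    ``theta``, each agent's next step is the sign of the displacement toward
    the other (so the distance strictly decreases, or an interaction fires if
    already co-located); beyond the threshold the headings are unchanged
    (returned as None).
    """
    d = max(abs(int(bx) - int(ax)), abs(int(by) - int(ay)))
    if d >= theta:
        return None
    a_head = (int(np.sign(bx - ax)), int(np.sign(by - ay)))
    b_head = (int(np.sign(ax - bx)), int(np.sign(ay - by)))
    return a_head, b_head


def attraction_field(occ: np.ndarray, theta: int):
    """Windowed target statistics for attraction steering.

    ``occ`` is a float occupancy array whose last two axes are grid x and y.
    Returns ``(cnt, sdx, sdy)``: for every position, the number of targets
    with Chebyshev distance < theta (window radius theta-1) and the summed x
    and y offsets toward them.  A source at a position with ``cnt > 0``
    steps ``(sign(sdx), sign(sdy))`` to move toward the local target centroid.
    """
    r = theta - 1
    ones = np.ones(2 * r + 1)
    offs = np.arange(-r, r + 1).astype(float)
    along_y = correlate1d(occ, ones, axis=-1, mode="constant")
    cnt = correlate1d(along_y, ones, axis=-2, mode="constant")
    sdx = correlate1d(along_y, offs, axis=-2, mode="constant")
    along_x = correlate1d(occ, ones, axis=-2, mode="constant")
    sdy = correlate1d(along_x, offs, axis=-1, mode="constant")
    return cnt, sdx, sdy


def import_mask(n: int, import_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli import decisions for n non-LPS molecules hitting a target."""
    return rng.random(n) < import_prob
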