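"""Low-level numeric kernels for the hot loops of the simulator.

Everything here is plain-ndarray in, plain-ndarray out, and written so the
same source compiles under numba when it is available and still runs (slowly)
as ordinary Python when it is not.  Seeding is handled by the callers: kernels
consume pre-drawn uniform variates, so compiled and interpreted runs of the
same seed produce bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np

try:  # numba is optional at runtime; the pure-Python path is identical
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def decorate(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return decorate


@njit(cache=True)
def _hull_chain(xs, ys, out):
    """Andrew's monotone chain on one frame.

    Writes the hull vertex indices in counter-clockwise order into ``out`` and
    returns their number k.  Collinear input collapses to k == 2 (the two
    extreme points); a single distinct point gives k == 1.
    """
    n = xs.shape[0]
    order = np.empty(n, np.int64)
    for i in range(n):
        order[i] = i
    for i in range(1, n):  # insertion sort, lexicographic by (x, y)
        j = i
        while j > 0:
            a = order[j - 1]
            b = order[j]
            if xs[a] > xs[b] or (xs[a] == xs[b] and ys[a] > ys[b]):
                order[j - 1] = b
                order[j] = a
                j -= 1
            else:
                break
    k = 0
    for ii in range(n):  # lower chain
        i = order[ii]
        while k >= 2 and (
            (xs[out[k - 1]] - xs[out[k - 2]]) * (ys[i] - ys[out[k - 2]])
            - (ys[out[k - 1]] - ys[out[k - 2]]) * (xs[i] - xs[out[k - 2]])
        ) <= 0.0:
            k -= 1
        out[k] = i
        k += 1
    lower = k + 1
    for ii in range(n - 2, -1, -1):  # upper chain
        i = order[ii]
        while k >= lower and (
            (xs[out[k - 1]] - xs[out[k - 2]]) * (ys[i] - ys[out[k - 2]])
            - (ys[out[k - 1]] - ys[out[k - 2]]) * (xs[i] - xs[out[k - 2]])
        ) <= 0.0:
            k -= 1
        out[k] = i
        k += 1
    return k - 1  # the closing vertex repeats the first


@njit(cache=True)
def hull_perimeter_area(xs, ys):
    """Perimeter and area of the convex hull of one frame.

    Degenerate conventions: a single distinct point gives (0, 0); collinear
    points give area 0 and perimeter equal to twice the extent (a closed
    out-and-back traversal of the segment).
    """
    n = xs.shape[0]
    out = np.empty(2 * n + 1, np.int64)
    k = _hull_chain(xs, ys, out)
    if k < 2:
        return 0.0, 0.0
    per = 0.0
    area2 = 0.0
    for i in range(k):
        a = out[i]
        b = out[(i + 1) % k]
        per += np.hypot(xs[b] - xs[a], ys[b] - ys[a])
        area2 += xs[a] * ys[b] - xs[b] * ys[a]
    return per, abs(area2) * 0.5


@njit(cache=True)
def hull_metrics_frames(frames):
    """Per-frame hull perimeter/area for a (T, N, 2) position stack."""
    t_len = frames.shape[0]
    res = np.empty((t_len, 2))
    for t in range(t_len):
        per, area = hull_perimeter_area(frames[t, :, 0], frames[t, :, 1])
        res[t, 0] = per
        res[t, 1] = area
    return res


@njit(cache=True)
def _fold(x, side):
    """Specular reflection of a scalar coordinate into [0, side]."""
    y = abs(x) % (2.0 * side)
    if y > side:
        y = 2.0 * side - y
    return y


@njit(cache=True)
def _mirror_sign(x, side):
    """-1 if the coordinate crossed an odd number of walls, else +1."""
    k = int(np.floor(x / side))
    if k % 2 == 0:
        return 1.0
    return -1.0


@njit(cache=True)
def _point_strictly_inside(px, py, xs, ys, hull, k, eps):
    """Strict interior test against a CCW hull given by indices hull[:k]."""
    for i in range(k):
        a = hull[i]
        b = hull[(i + 1) % k]
        cross = (xs[b] - xs[a]) * (py - ys[a]) - (ys[b] - ys[a]) * (px - xs[a])
        if cross <= eps:
            return False
    return True


@njit(cache=True)
def walk_with_rule(
    pos0,
    hd0,
    step,
    width,
    height,
    turn_prob,
    retreat_prob,
    radius,
    u_turn,
    new_heading,
    u_rule,
    cand_heading,
):
    """Correlated random walk with the vertex-retreat interaction rule.

    Agents advance a fixed ``step`` per tick and redraw their heading
    uniformly with probability ``turn_prob``.  Before moving, an agent that is
    a vertex of the group's convex hull and has no conspecific within
    ``radius`` redirects, with probability ``retreat_prob``, onto a heading
    whose next position lies strictly inside the current hull (headings drawn
    uniformly by rejection from ``cand_heading``; if none of the candidates
    enters the hull, the agent heads for the hull centroid).  Walls reflect
    specularly.  All random inputs are pre-drawn uniforms of shapes (T, N) and
    (T, N, K); the kernel itself is deterministic.
    """
    ticks = u_turn.shape[0]
    n = pos0.shape[0]
    n_cand = cand_heading.shape[2]
    frames = np.empty((ticks, n, 2))
    xs = pos0[:, 0].copy()
    ys = pos0[:, 1].copy()
    hd = hd0.copy()
    hull = np.empty(2 * n + 1, np.int64)
    is_vertex = np.empty(n, np.bool_)
    for t in range(ticks):
        for i in range(n):
            if u_turn[t, i] < turn_prob:
                hd[i] = new_heading[t, i]
        if n >= 3:
            k = _hull_chain(xs, ys, hull)
            if k >= 3:  # a degenerate (collinear) hull skips the rule
                for i in range(n):
                    is_vertex[i] = False
                for i in range(k):
                    is_vertex[hull[i]] = True
                for i in range(n):
                    if not is_vertex[i]:
                        continue
                    isolated = True
                    for j in range(n):
                        if j == i:
                            continue
                        dx = xs[j] - xs[i]
                        dy = ys[j] - ys[i]
                        if dx * dx + dy * dy < radius * radius:
                            isolated = False
                            break
                    if not isolated or u_rule[t, i] >= retreat_prob:
                        continue
                    accepted = False
                    for c in range(n_cand):
                        ang = cand_heading[t, i, c]
                        px = xs[i] + step * np.cos(ang)
                        py = ys[i] + step * np.sin(ang)
                        if _point_strictly_inside(px, py, xs, ys, hull, k, 1e-12):
                            hd[i] = ang
                            accepted = True
                            break
                    if not accepted:
                        cx = 0.0
                        cy = 0.0
                        for j in range(n):
                            cx += xs[j]
                            cy += ys[j]
                        cx /= n
                        cy /= n
                        hd[i] = np.arctan2(cy - ys[i], cx - xs[i])
        for i in range(n):
            vx = step * np.cos(hd[i])
            vy = step * np.sin(hd[i])
            nx = xs[i] + vx
            ny = ys[i] + vy
            sx = _mirror_sign(nx, width)
            sy = _mirror_sign(ny, height)
            xs[i] = _fold(nx, width)
            ys[i] = _fold(ny, height)
            hd[i] = np.arctan2(vy * sy, vx * sx)
            frames[t, i, 0] = xs[i]
            frames[t, i, 1] = ys[i]
    return frames


# Uncompiled references (identical source) for cross-checking the compiled path.
if HAVE_NUMBA:
    hull_perimeter_area_py = hull_perimeter_area.py_func
    walk_with_rule_py = walk_with_rule.py_func
else:  # pragma: no cover
    hull_perimeter_area_py = hull_perimeter_area
    walk_with_rule_py = walk_with_rule
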