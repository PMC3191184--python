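"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions with plain Python loops,
deliberately sharing no code with the package.
"""

import math


def brute_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    da = math.sqrt(sum((ai - ma) ** 2 for ai in a))
    db = math.sqrt(sum((bi - mb) ** 2 for bi in b))
    return num / (da * db)


def brute_manders(a, b):
    m1 = sum(ai for ai, bi in zip(a, b) if bi > 0) / sum(a)
    m2 = sum(bi for ai, bi in zip(a, b) if ai > 0) / sum(b)
    return m1, m2


def brute_icq(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    positive = sum(1 for ai, bi in zip(a, b) if (ai - ma) * (bi - mb) > 0)
    return positive / n - 0.5


def brute_pixels_in_polygon(vertices, shape):
    """Pixel centres inside a polygon, via ray casting + on-edge check."""
    hits = []
    nv = len(vertices)
    for r in range(shape[0]):
        for c in range(shape[1]):
            x, y = float(c), float(r)
            inside = False
            on_edge = False
            for i in range(nv):
                x1, y1 = vertices[i]
                x2, y2 = vertices[(i + 1) % nv]
                if _on_segment(x, y, x1, y1, x2, y2):
                    on_edge = True
                    break
                if (y1 > y) != (y2 > y):
                    xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xint:
                        inside = not inside
            if inside or on_edge:
                hits.append((r, c))
    return hits


def brute_pixels_near_polyline(vertices, width, shape):
    """Pixel centres within width/2 of any path segment (inclusive)."""
    hits = []
    half = width / 2.0
    for r in range(shape[0]):
        for c in range(shape[1]):
            d = min(
                _point_segment_distance(c, r, *vertices[i], *vertices[i + 1])
                for i in range(len(vertices) - 1)
            )
            if d <= half:
                hits.append((r, c))
    return hits


def _on_segment(px, py, x1, y1, x2, y2, eps=1e-9):
    return _point_segment_distance(px, py, x1, y1, x2, y2) <= eps


def _point_segment_distance(px, py, x1, y1, x2, y2):
    dx, dy = x2 - x1, y2 - y1
    if dx == dy == 0:
        return math.hypot(px - x1, py - y1)
    t = max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / (dx * dx + dy * dy)))
    return math.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def brute_connected_components(binary):
    """8-connected components by flood fill; returns list of pixel sets."""
    h = len(binary)
    w = len(binary[0])
    seen = [[False] * w for _ in range(h)]
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r][c] and not seen[r][c]:
                stack = [(r, c)]
                seen[r][c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if 0 <= r2 < h and 0 <= c2 < w and binary[r2][c2] and not seen[r2][c2]:
                                seen[r2][c2] = True
                                stack.append((r2, c2))
                comps.append(frozenset(comp))
    return comps
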