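"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the operation *definitions* (per-pixel
interval recheck, neighborhood scans, BFS flood fill) and shares no code
with the package paths it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def naive_segment(hsv: np.ndarray, h_lo, h_hi, s_lo, s_hi, v_lo, v_hi) -> np.ndarray:
    """Per-pixel recheck of the three-interval conjunction, python loops."""
    out = np.zeros(hsv.shape[:2], dtype=np.uint8)
    for r in range(hsv.shape[0]):
        for c in range(hsv.shape[1]):
            h, s, v = int(hsv[r, c, 0]), int(hsv[r, c, 1]), int(hsv[r, c, 2])
            if h_lo <= h <= h_hi and s_lo <= s <= s_hi and v_lo <= v <= v_hi:
                out[r, c] = 255
    return out


def naive_erode(mask: np.ndarray) -> np.ndarray:
    """3x3 square erosion by definition; outside the frame is background."""
    fg = mask > 0
    rows, cols = fg.shape
    out = np.zeros_like(fg)
    for r in range(rows):
        for c in range(cols):
            keep = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols and fg[rr, cc]):
                        keep = False
            out[r, c] = keep
    return np.where(out, 255, 0).astype(np.uint8)


def naive_dilate(mask: np.ndarray) -> np.ndarray:
    """3x3 square dilation by definition; nothing contributed from outside."""
    fg = mask > 0
    rows, cols = fg.shape
    out = np.zeros_like(fg)
    for r in range(rows):
        for c in range(cols):
            hit = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and fg[rr, cc]:
                        hit = True
            out[r, c] = hit
    return np.where(out, 255, 0).astype(np.uint8)


def naive_open(mask: np.ndarray) -> np.ndarray:
    return naive_dilate(naive_erode(mask))


def flood_fill_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """All maximal 8-connected foreground regions via BFS flood fill."""
    fg = mask > 0
    rows, cols = fg.shape
    seen = np.zeros_like(fg)
    comps = []
    for r0 in range(rows):
        for c0 in range(cols):
            if not fg[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and fg[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def all_pairs_earliest_valid(events, line_of):
    """Exhaustive scan over ordered index pairs for the earliest valid one."""
    best = None
    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            if line_of(events[i][0]) != line_of(events[j][0]):
                if best is None or (i, j) < best[:2]:
                    best = (i, j, events[i][0], events[j][0],
                            events[j][1] - events[i][1])
    return best
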