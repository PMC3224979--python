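"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops, linear
scans) and shares no code with the package beyond the documented algorithm
semantics.
"""

from __future__ import annotations

import numpy as np

OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def mean_four_frames(frames: list[np.ndarray]) -> np.ndarray:
    """Per-pixel arithmetic mean via an explicit loop."""
    h, w = frames[0].shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = sum(f[y, x] for f in frames) / len(frames)
    return out


def conv2d_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop 2-D convolution with reflective border handling."""
    h, w = img.shape
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    padded = np.pad(img, ((ry, ry), (rx, rx)), mode="reflect")
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    acc += kernel[i, j] * padded[y + kh - 1 - i, x + kw - 1 - j]
            out[y, x] = acc
    return out


def erode_window(img: np.ndarray, offsets: list[tuple[int, int]]) -> np.ndarray:
    """Grayscale erosion as an explicit sliding min over a structuring element."""
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy, dx in offsets:
                yy = min(max(y + dy, 0), h - 1)  # replicate ~ reflect for r<=1 tests
                xx = min(max(x + dx, 0), w - 1)
                vals.append(img[yy, xx])
            out[y, x] = min(vals)
    return out


def dilate_window(img: np.ndarray, offsets: list[tuple[int, int]]) -> np.ndarray:
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy, dx in offsets:
                yy = min(max(y + dy, 0), h - 1)
                xx = min(max(x + dx, 0), w - 1)
                vals.append(img[yy, xx])
            out[y, x] = max(vals)
    return out


def regional_minima(img: np.ndarray) -> np.ndarray:
    """8-connected regional minima by plateau flood fill."""
    h, w = img.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            level = img[sy, sx]
            plateau = [(sy, sx)]
            visited[sy, sx] = True
            is_min = True
            i = 0
            while i < len(plateau):
                y, x = plateau[i]
                i += 1
                for dy, dx in OFFSETS8:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w):
                        continue
                    if img[ny, nx] == level:
                        if not visited[ny, nx]:
                            visited[ny, nx] = True
                            plateau.append((ny, nx))
                    elif img[ny, nx] < level:
                        is_min = False
            if is_min:
                for y, x in plateau:
                    out[y, x] = True
    return out


def watershed_flood(img: np.ndarray, marker_labels: np.ndarray) -> np.ndarray:
    """Priority-flood watershed with Meyer's dam rule, via linear frontier scans.

    Semantics: marker pixels are settled with their labels; neighbours are
    queued with (value, age) priority, ages assigned while scanning marker
    pixels in raster order and neighbours in the fixed 8-offset order; the
    queued pixel with the smallest (value, age) is processed next; a pixel
    whose settled neighbours carry one distinct label joins that basin and
    queues its own unqueued neighbours, one with two or more labels becomes
    a dam (label 0); pixels never reached stay 0.
    """
    h, w = img.shape
    out = np.asarray(marker_labels, dtype=np.int64).copy()
    settled = out > 0
    queued = settled.copy()
    frontier: list[tuple[float, int, int, int]] = []
    age = 0
    for y in range(h):
        for x in range(w):
            if not settled[y, x]:
                continue
            for dy, dx in OFFSETS8:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and not queued[ny, nx]:
                    queued[ny, nx] = True
                    frontier.append((float(img[ny, nx]), age, ny, nx))
                    age += 1
    while frontier:
        best = 0
        for i in range(1, len(frontier)):
            if frontier[i][:2] < frontier[best][:2]:
                best = i
        _, _, y, x = frontier.pop(best)
        labels_seen = set()
        for dy, dx in OFFSETS8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and settled[ny, nx]:
                labels_seen.add(int(out[ny, nx]))
        if len(labels_seen) != 1:
            continue  # dam (>=2) or orphan (0): stays label 0, spreads nothing
        out[y, x] = labels_seen.pop()
        settled[y, x] = True
        for dy, dx in OFFSETS8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not queued[ny, nx]:
                queued[ny, nx] = True
                frontier.append((float(img[ny, nx]), age, ny, nx))
                age += 1
    return out


def pearson_flat(a: np.ndarray, m: np.ndarray) -> float:
    """Pearson correlation of two flattened binary images, by the textbook sums."""
    av = [float(v) for v in np.asarray(a).ravel()]
    mv = [float(v) for v in np.asarray(m).ravel()]
    n = len(av)
    ma = sum(av) / n
    mm = sum(mv) / n
    num = sum((x - ma) * (y - mm) for x, y in zip(av, mv))
    da = sum((x - ma) ** 2 for x in av)
    dm = sum((y - mm) ** 2 for y in mv)
    return num / (da * dm) ** 0.5


def percent_error_counts(a: np.ndarray, m: np.ndarray) -> float:
    na = int(sum(1 for v in np.asarray(a).ravel() if v == 1))
    nm = int(sum(1 for v in np.asarray(m).ravel() if v == 1))
    return 100.0 * abs(na - nm) / nm


def error_sum_counts(a: np.ndarray, m: np.ndarray) -> float:
    a = np.asarray(a).ravel()
    m = np.asarray(m).ravel()
    fp = sum(1 for x, y in zip(a, m) if x == 1 and y == 0)
    fn = sum(1 for x, y in zip(a, m) if x == 0 and y == 1)
    nm = sum(1 for y in m if y == 1)
    return 100.0 * (fp + fn) / nm


def rmsd_paired(pa: np.ndarray, pm: np.ndarray) -> float:
    """RMS distance over already-paired point lists, by explicit summation."""
    total = 0.0
    for (xa, ya), (xm, ym) in zip(pa, pm):
        total += (float(xa) - float(xm)) ** 2 + (float(ya) - float(ym)) ** 2
    return (total / len(pa)) ** 0.5


def random_blob_mask(rng: np.random.Generator, shape=(16, 16)) -> np.ndarray:
    """A random nonempty single-component 8-connected mask (for contour tests)."""
    from scipy import ndimage as ndi

    while True:
        mask = (rng.random(shape) < 0.45).astype(np.uint8)
        mask = ndi.binary_closing(mask, structure=np.ones((2, 2))).astype(np.uint8)
        lab, n = ndi.label(mask, structure=np.ones((3, 3)))
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = int(np.argmax(sizes))
        out = (lab == keep).astype(np.uint8)
        if out.sum() >= 4:
            return out
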