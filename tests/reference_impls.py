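"""Independent reference implementations used as test oracles.

Deliberately written in a plain, loop-based style, sharing no code with the
package: a brute-force SNR peak finder (hand-rolled BFS connectivity), a
direct O(N^4) circular autocorrelation, a by-hand byte-offset decoder and a
list-based iterative outlier-rejection trainer.
"""

from __future__ import annotations

import struct

import numpy as np

STD_FLOOR = 1e-6


def brute_force_find_peaks(frame, params, mask=None):
    """Row-by-row re-implementation of the SNR Bragg-peak search.

    Returns a list of dict rows with the same fields and ordering convention
    as the package's peak table.
    """
    frame = [list(map(float, row)) for row in np.asarray(frame)]
    nrows, ncols = len(frame), len(frame[0])
    if mask is None:
        bad = [[False] * ncols for _ in range(nrows)]
    else:
        bad = [[bool(v) for v in row] for row in np.asarray(mask)]
    h = params.box_half_width
    used = [[False] * ncols for _ in range(nrows)]
    rows_out = []

    for r in range(nrows):
        for c in range(ncols):
            if bad[r][c] or used[r][c]:
                continue
            if frame[r][c] <= params.pixel_threshold:
                continue
            if r - h < 0 or r + h >= nrows or c - h < 0 or c + h >= ncols:
                continue

            # strict box max with first-in-row-major tie-break
            box_vals = []
            vmax, argmax = None, None
            for br in range(r - h, r + h + 1):
                for bc in range(c - h, c + h + 1):
                    if bad[br][bc]:
                        continue
                    v = frame[br][bc]
                    box_vals.append(v)
                    if vmax is None or v > vmax:
                        vmax, argmax = v, (br, bc)
            if argmax != (r, c):
                continue

            # iterative one-sided background stripping
            vals = list(box_vals)
            while vals:
                mean = sum(vals) / len(vals)
                var = sum((v - mean) ** 2 for v in vals) / len(vals)
                std = var**0.5
                kept = [v for v in vals if (v - mean) <= params.snr_background * max(std, STD_FLOOR)]
                if len(kept) == len(vals) or not kept:
                    break
                vals = kept
            std = max(std, STD_FLOOR)

            # BFS over 8-connected above-SNR pixels from the seed
            def above(br, bc):
                return (not bad[br][bc]) and (frame[br][bc] - mean) / std > params.snr_peak

            members = set()
            if above(r, c):
                queue = [(r, c)]
                members.add((r, c))
                while queue:
                    qr, qc = queue.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = qr + dr, qc + dc
                            if (nr, nc) in members:
                                continue
                            if r - h <= nr <= r + h and c - h <= nc <= c + h and above(nr, nc):
                                members.add((nr, nc))
                                queue.append((nr, nc))
            if len(members) < params.min_npix:
                continue

            wsum = sum(frame[mr][mc] - mean for mr, mc in members)
            rows_out.append({
                "centroid_row": sum((frame[mr][mc] - mean) * mr for mr, mc in members) / wsum,
                "centroid_col": sum((frame[mr][mc] - mean) * mc for mr, mc in members) / wsum,
                "center_index": r * ncols + c,
                "max_value": max(frame[mr][mc] for mr, mc in members),
                "integrated": wsum,
                "npix": len(members),
            })
            for mr, mc in members:
                used[mr][mc] = True
    return rows_out


def direct_autocorrelation(image):
    """O(N^4) circular autocorrelation by explicit shifting sums."""
    image = np.asarray(image, dtype=float)
    nr, nc = image.shape
    out = np.zeros((nr, nc))
    for dr in range(nr):
        for dc in range(nc):
            total = 0.0
            for r in range(nr):
                for c in range(nc):
                    total += image[r, c] * image[(r + dr) % nr, (c + dc) % nc]
            out[dr, dc] = total
    return out


def hand_decode_byte_offset(payload: bytes):
    """Step-through decoder of the byte-offset stream, written from the rules."""
    values = []
    current = 0
    i = 0
    while i < len(payload):
        byte = payload[i]
        if byte != 0x80:
            delta = byte - 256 if byte > 127 else byte
            i += 1
        else:
            delta = struct.unpack("<h", payload[i + 1: i + 3])[0]
            i += 3
            if delta == -32768:
                delta = struct.unpack("<i", payload[i: i + 4])[0]
                i += 4
        current = ((current + delta + 2**31) % 2**32) - 2**31  # int32 wrap
        values.append(current)
    return values


def list_based_rejection_train(values, n_outlier, max_passes=20, floor=1e-6):
    """Iterative outlier rejection over one pixel's value list.

    Returns (mean, std, count) after convergence, mirroring the documented
    training rule with a population standard deviation.
    """
    vals = [float(v) for v in values]
    for _ in range(max_passes):
        mean = sum(vals) / len(vals)
        std = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
        kept = [v for v in vals if abs(v - mean) <= n_outlier * max(std, floor)]
        if not kept:
            break
        if len(kept) == len(vals):
            return mean, std, len(vals)
        vals = kept
    mean = sum(vals) / len(vals)
    std = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
    return mean, std, len(vals)
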