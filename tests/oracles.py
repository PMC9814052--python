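"""Brute-force reference implementations used as independent test oracles."""

import numpy as np


def brute_force_strong_pixels(image, w, snr_min, sentinel, n_iter):
    """Double-loop strong-pixel selection with iterative background
    refinement; deliberately naive and independent of the vectorized path."""
    rows, cols = image.shape
    strong = np.zeros(image.shape, dtype=bool)
    for _ in range(n_iter):
        new = np.zeros_like(strong)
        for r in range(rows):
            for c in range(cols):
                if image[r, c] == sentinel:
                    continue
                vals = []
                for rr in range(max(0, r - w), min(rows, r + w + 1)):
                    for cc in range(max(0, c - w), min(cols, c + w + 1)):
                        if image[rr, cc] != sentinel and not strong[rr, cc]:
                            vals.append(float(image[rr, cc]))
                if not vals:
                    continue
                mean = np.mean(vals)
                sd = np.sqrt(np.mean([(v - mean) ** 2 for v in vals]))
                if image[r, c] > mean + snr_min * sd:
                    new[r, c] = True
        if np.array_equal(new, strong):
            break
        strong = new
    return strong
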