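"""Shared test utilities: tiny renderers and brute-force oracles."""

import numpy as np
from scipy import ndimage


def render_disk(shape, cy, cx, r, intensity=200.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r,
                    intensity, 0.0)


def oracle_components(frame, params):
    """Exhaustive flood-fill oracle: per threshold level, connected
    components passing only the area filter, merged across levels by the
    same center-distance rule as the detector."""
    centers = []
    thresholds = np.arange(params.min_threshold, params.max_threshold,
                           params.threshold_step)
    for thr in thresholds:
        binary = frame >= thr
        labels, n = ndimage.label(binary, structure=np.ones((3, 3)))
        for lab in range(1, n + 1):
            ys, xs = np.nonzero(labels == lab)
            if params.a_min <= len(ys) <= params.a_max:
                centers.append((xs.mean(), ys.mean()))
    clusters = []
    for cx, cy in centers:
        placed = False
        for cl in clusters:
            mx = np.mean([p[0] for p in cl])
            my = np.mean([p[1] for p in cl])
            if (mx - cx) ** 2 + (my - cy) ** 2 <= params.min_dist ** 2:
                cl.append((cx, cy))
                placed = True
                break
        if not placed:
            clusters.append([(cx, cy)])
    return [(np.mean([p[0] for p in c]), np.mean([p[1] for p in c]))
            for c in clusters if len(c) >= params.min_repeatability]
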