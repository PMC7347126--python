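"""Shared fixtures and independent test oracles."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from memclust import imaging, synthetic


def flood_fill_labels(mask: np.ndarray, connectivity: int, periodic: bool) -> np.ndarray:
    """Recursive-style (BFS) flood-fill labeling oracle, independent of the
    union-find implementation under test."""
    occ = np.asarray(mask).astype(bool)
    h, w = occ.shape
    if connectivity == 4:
        offs = [(0, -1), (0, 1), (-1, 0), (1, 0)]
    else:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if not occ[i, j] or labels[i, j]:
                continue
            current += 1
            queue = deque([(i, j)])
            labels[i, j] = current
            while queue:
                y, x = queue.popleft()
                for di, dj in offs:
                    ny, nx = y + di, x + dj
                    if periodic:
                        ny %= h
                        nx %= w
                    elif not (0 <= ny < h and 0 <= nx < w):
                        continue
                    if occ[ny, nx] and not labels[ny, nx]:
                        labels[ny, nx] = current
                        queue.append((ny, nx))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> bool:
    """True iff two labelings agree up to a permutation of label names."""
    pa, pb = a[mask], b[mask]
    return (
        len(set(zip(pa.tolist(), pb.tolist())))
        == len(set(pa.tolist()))
        == len(set(pb.tolist()))
    )


@pytest.fixture(scope="session")
def default_scene():
    """Default synthetic scenario, its ground truth and rendered stack."""
    scenario = synthetic.Scenario(seed=0)
    truth = synthetic.build_ground_truth(scenario)
    stack = synthetic.render_stack(truth, scenario)
    return scenario, truth, stack


@pytest.fixture(scope="session")
def steep_scene():
    """Same acquisition with a steeper planted size exponent."""
    scenario = synthetic.Scenario(seed=0, alpha_target=3.0)
    truth = synthetic.build_ground_truth(scenario)
    stack = synthetic.render_stack(truth, scenario)
    return scenario, truth, stack


def recovered_alpha(scenario, stack) -> float:
    """End-to-end exponent recovery: segment, label, calibrate sizes, fit."""
    sizes = synthetic.recover_steady_sizes(stack, scenario)
    corrected = synthetic.correct_sizes(sizes, synthetic.size_calibration(scenario))
    dist = imaging.size_distribution(corrected)
    fit = imaging.fit_power_law(
        dist, (5.0, float(np.percentile(corrected, 99.5)))
    )
    return fit.alpha
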