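import numpy as np
import pytest

from whealsim.classifier import WhealMask


def make_disk(n, ci, cj, r):
    ii, jj = np.mgrid[0:n, 0:n]
    return (ii - ci) ** 2 + (jj - cj) ** 2 <= r ** 2


def make_ring(n, ci, cj, r_out, r_in):
    return make_disk(n, ci, cj, r_out) & ~make_disk(n, ci, cj, r_in)


def flood_fill_components(mask, connectivity=8):
    """Independent BFS connected-component labelling (test oracle)."""
    mask = np.asarray(mask, bool)
    n, m = mask.shape
    labels = np.zeros((n, m), int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for i in range(n):
        for j in range(m):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    a, b = stack.pop()
                    for da, db in nbrs:
                        x, y = a + da, b + db
                        if (0 <= x < n and 0 <= y < m and mask[x, y]
                                and labels[x, y] == 0):
                            labels[x, y] = current
                            stack.append((x, y))
    return labels, current


def flood_fill_holes(mask):
    """Hole inventory per component via an independent reachability oracle.

    For one component, its holes are everything outside the component that
    cannot reach the image border through 4-connected non-component pixels
    (other components inside a hole count as hole area). Returns
    ``{component_label: (hole_count, hole_area)}``.
    """
    mask = np.asarray(mask, bool)
    comp_labels, n_comp = flood_fill_components(mask, connectivity=8)
    n, m = mask.shape
    holes = {}
    for k in range(1, n_comp + 1):
        outside = comp_labels != k
        reach = np.zeros((n, m), bool)
        stack = [(i, j) for i in range(n) for j in (0, m - 1)
                 if outside[i, j]]
        stack += [(i, j) for j in range(m) for i in (0, n - 1)
                  if outside[i, j]]
        for i, j in stack:
            reach[i, j] = True
        while stack:
            a, b = stack.pop()
            for da, db in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                x, y = a + da, b + db
                if (0 <= x < n and 0 <= y < m and outside[x, y]
                        and not reach[x, y]):
                    reach[x, y] = True
                    stack.append((x, y))
        hole_px = outside & ~reach
        _, n_holes = flood_fill_components(hole_px, connectivity=4)
        holes[k] = (n_holes, int(hole_px.sum()))
    return comp_labels, holes


@pytest.fixture
def ring_mask():
    return WhealMask(make_ring(64, 32, 32, 20, 12), pixel_size_cm=0.1)
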