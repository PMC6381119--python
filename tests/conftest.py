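import numpy as np
import pytest

from dicentric.segmentation import ChromosomeObject


def obj_from_mask(mask, gray=None, object_id=1):
    """Wrap a boolean mask (with optional gray crop) as a ChromosomeObject."""
    mask = np.asarray(mask, dtype=bool)
    if gray is None:
        gray = np.full(mask.shape, 60, dtype=np.uint8)
    return ChromosomeObject(
        object_id=object_id,
        mask=mask,
        bbox=(0, 0, mask.shape[0], mask.shape[1]),
        gray_crop=np.asarray(gray, dtype=np.uint8),
        area_px=int(mask.sum()),
    )


def bfs_watershed_oracle(mask, seeds):
    """Brute-force reference for seeded region growth.

    Geodesic (8-connected, unit cost) BFS distance from every seed; each
    pixel takes the label of the nearest seed, ties to the lower seed id.
    """
    from collections import deque

    H, W = mask.shape
    INF = 10**9
    dists = []
    for seed in seeds:
        d = np.full((H, W), INF, dtype=np.int64)
        q = deque()
        for r, c in np.argwhere(seed):
            d[r, c] = 0
            q.append((r, c))
        while q:
            r, c = q.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and d[rr, cc] > d[r, c] + 1:
                        d[rr, cc] = d[r, c] + 1
                        q.append((rr, cc))
        dists.append(d)
    dists = np.stack(dists)
    labels = np.zeros((H, W), dtype=np.int32)
    for r, c in np.argwhere(mask):
        col = dists[:, r, c]
        best = col.min()
        labels[r, c] = int(np.argmin(col)) + 1 if best < INF else 0
    return labels


def random_blob_mask(rng, size=48):
    """A connected random blob mask for watershed property tests."""
    from scipy import ndimage as ndi
    from skimage import measure

    field = rng.normal(size=(size, size))
    field = ndi.gaussian_filter(field, sigma=4)
    mask = field > np.percentile(field, 65)
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 4 : 3 * size // 4, size // 4 : 3 * size // 4] = True
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


@pytest.fixture(scope="session")
def singles_corpus():
    """20 clean single-chromosome phantoms (alternating mono/dicentric)."""
    from dicentric.phantoms import make_single_chromosome_image

    corpus = []
    for s in range(20):
        n = 1 + (s % 2)
        img, truth = make_single_chromosome_image(n_centromeres=n, seed=s)
        corpus.append((img, truth))
    return corpus
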