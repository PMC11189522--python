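"""2-D projection of per-sequence representations for visualisation."""

from __future__ import annotations

import numpy as np


def project_2d(
    embeddings: np.ndarray, seed: int = 0, n_neighbors: int = 15
) -> np.ndarray:
    """UMAP projection of an (n, d) embedding matrix to (n, 2) coordinates.

    The neighbourhood size is capped at n - 1; fewer than 10 rows is an
    error (a meaningful neighbour embedding needs some data).  Fixed seed
    plus identical input gives identical output.
    """
    embeddings = np.asarray(embeddings)
    if embeddings.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    n = embeddings.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows to project")
    import umap  # deferred: slow import, only needed here

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=0.0,  # identical inputs may coincide in the layout
        random_state=seed,
        n_jobs=1,
    )
    return np.asarray(reducer.fit_transform(embeddings), dtype=float)
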