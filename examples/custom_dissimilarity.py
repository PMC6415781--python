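"""Cluster any user-supplied dissimilarity matrix.

The method needs nothing but a symmetric pairwise dissimilarity with zero
diagonal - the objects need not live in any metric space and the triangle
inequality is not required.  Here six abstract states form two tight
groups plus a loner; the dendrogram finds that organization by itself.
"""

import numpy as np

from scsc import AdjacencyMatrix, converged_clusters
from scsc.pipeline import color_and_code

# states 0-2 alike, states 3-4 alike, state 5 unlike everything
values = np.array(
    [
        [0.0, 0.1, 0.2, 1.0, 1.1, 2.0],
        [0.1, 0.0, 0.1, 1.2, 1.0, 2.1],
        [0.2, 0.1, 0.0, 1.1, 1.0, 2.2],
        [1.0, 1.2, 1.1, 0.0, 0.1, 2.0],
        [1.1, 1.0, 1.0, 0.1, 0.0, 2.1],
        [2.0, 2.1, 2.2, 2.0, 2.1, 0.0],
    ]
)
A = AdjacencyMatrix(values, labels=list("abcdef"))

solution, codes, tree = color_and_code(A, max_depth=2)
print("eigenvalues (descending):", np.round(solution.eigenvalues, 4))
print("state codes:", dict(zip(A.labels, codes.strings)))
print("newick:", tree.to_newick())
print("clusters:", [[A.labels[i] for i in c] for c in converged_clusters(tree)])
print()
print("Large branch lengths (in merit z units) mark strong separations;")
print("the loner 'f' splits off first, then the two groups part.")
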