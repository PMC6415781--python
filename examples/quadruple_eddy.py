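"""Recover the four eddy cores of the unsteady quadruple-eddy flow.

300 drifters are seeded uniformly, advected for four oscillation periods,
and clustered by the coloring dendrogram.  The printed table lists the
sizable converged clusters: four of them are quadrant-bound eddy cores
(high stay fraction), the rest is chaotic residue that wanders between
quadrants.
"""

from scsc.benchmarks import quadruple_eddy_structure, retained_fraction

result = quadruple_eddy_structure(n=300, seed=0, depth=7)
tree = result.tree

print(f"recovered four quadrant cores: {result.recovered}")
print(f"coherent-core branch: {result.core_branch!r} "
      f"(completed at level {result.detail['level']})")
print()
print("code     members  width  retained")
for node in result.clusters:
    print(
        f"{node.prefix:<8s} {node.count:7d}  {node.width:5.3f}  "
        f"{retained_fraction(tree, node):8.3f}"
    )
print(f"quadrants covered (east?, north?): {result.detail['quadrants']}")
print()
print("A retained fraction near 1 means the cluster no longer changes as")
print("more eigenvectors are added - the convergence that marks a real")
print("coherent structure.")
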