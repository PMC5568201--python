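import numpy as np
import pandas as pd
import pytest

from introphy.alignment import IUPACAlignment


def make_alignment(rows: dict[str, str], loci: pd.DataFrame | None = None) -> IUPACAlignment:
    taxa = list(rows)
    matrix = np.vstack(
        [np.frombuffer(rows[t].encode(), dtype="S1") for t in taxa]
    )
    return IUPACAlignment(taxa=taxa, matrix=matrix, loci=loci)


@pytest.fixture
def small_alignment() -> IUPACAlignment:
    #                 0123456789
    return make_alignment(
        {
            "t1": "ACGTRYSWKM",
            "t2": "ACGTAAACGT",
            "t3": "ACGTNN--GT",
        }
    )


def tree_metric(tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a rooted Tree (test oracle)."""
    depth = {tree.root: 0.0}
    for n in tree.preorder():
        for c in n.children:
            depth[c] = depth[n] + c.length
    leaves = tree.leaves()
    chains = {}
    for leaf in leaves:
        chain, x = [], leaf
        while x is not None:
            chain.append(x)
            x = x.parent
        chains[leaf] = chain
    names = [l.name for l in leaves]
    d = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(leaves):
        seta = set(chains[a])
        for b in leaves[i + 1:]:
            lca = next(x for x in chains[b] if x in seta)
            val = depth[a] + depth[b] - 2 * depth[lca]
            d.loc[a.name, b.name] = d.loc[b.name, a.name] = val
    return d
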