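"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: the Dollo
oracle is a Sankoff-style cost DP on nested tuples, the stop-codon
oracle translates with Biopython, and the initiation-candidate oracle
is a direct window scan.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq

INF = float("inf")


# --- Dollo parsimony -------------------------------------------------------


def dollo_min_oracle(tree, states) -> int:
    """Minimum number of loss edges for a single-gain character.

    ``tree`` is a nested tuple whose leaves are label strings; ``states``
    maps label -> functional/lost/unknown. The character is present on
    the stem; a loss on the stem edge itself (cost 1) covers the
    all-lost corner.
    """

    def rec(node):
        if isinstance(node, str):
            st = states[node]
            if st == "functional":
                return 0, INF
            if st == "lost":
                return INF, 0
            return 0, 0  # unknown: free either way
        cost_present = 0.0
        cost_absent = 0.0
        for child in node:
            p, a = rec(child)
            cost_present += min(p, a + 1)
            cost_absent += a
        return cost_present, cost_absent

    present, absent = rec(tree)
    return int(min(present, absent + 1))


def all_rooted_trees(labels):
    """Every rooted binary leaf-labelled tree as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], list(labels[1:])
    for t in all_rooted_trees(rest):
        yield from _insert_everywhere(t, first)


def _insert_everywhere(t, leaf):
    yield (leaf, t)
    if not isinstance(t, str):
        for i, child in enumerate(t):
            for sub in _insert_everywhere(child, leaf):
                yield t[:i] + (sub,) + t[i + 1 :]


def to_newick(t) -> str:
    def rec(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(rec(c) for c in node) + ")"

    return rec(t) + ";"


# --- premature stops -------------------------------------------------------


def stop_codon_indices(row: str, ann) -> list[int]:
    """Codon indices (from ATG1's column) translating to a stop."""
    seq = "".join(
        row[c] for c in range(ann.atg1_pos, ann.donor_pos) if row[c] != "-"
    )
    seq = seq[: len(seq) // 3 * 3]
    if not seq:
        return []
    aa = str(Seq(seq).translate())
    return [i for i, ch in enumerate(aa) if ch == "*"]


# --- initiation candidates -------------------------------------------------


def candidate_sites_oracle(seq: str) -> set[tuple[int, str]]:
    seq = seq.upper().replace("U", "T")
    out = {(m.start(), "ATG") for m in re.finditer(r"(?=ATG)", seq)}
    for pos in range(len(seq) - 2):
        codon = seq[pos : pos + 3]
        if codon == "ATG" or sum(a != b for a, b in zip(codon, "ATG")) != 1:
            continue
        minus3 = seq[pos - 3] if pos >= 3 else ""
        plus4 = seq[pos + 3] if pos + 3 < len(seq) else ""
        if minus3 in "AG" and plus4 == "G":
            out.add((pos, codon))
    return out
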