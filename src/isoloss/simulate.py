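"""Synthetic trees, lesioned alignments, constructs and read counts.

Every stage of the pipeline is testable without downloads: a template
exon-1A-like region with annotated functional blocks evolves neutrally
down a species tree (point substitutions only, alignment columns
preserved), branch-anchored lesions are planted clade-wide with exact
ground truth, read counts are drawn under known isoform molar ratios,
and a packaged fixture transcribes the attested per-species states of
the mammalian survey (promoter rearrangement shared by muroids,
independent coding lesions in Ctenomys and Octodon, promoter deletion
plus stop in Echinops, whole-region absence in Erinaceus, splice-donor
loss in Sus and Sorex, ATG2-only initiation in Equus and Vicugna).

Background substitutions never spontaneously create loss lesions:
start codons and the donor are protected and coding substitutions that
would create an in-frame stop are skipped, so truth tables are exact.
Pass ``protect=False`` for stress testing (excluded from exact-recovery
guarantees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .annotation import GAP, FeatureAnnotation, RegionAlignment, RegionRow
from .calling import State
from .expression import ExonModel
from .features import STOP_CODONS, LesionType
from .initiation import Construct

BASES = np.array(list("ACGT"))

# template geometry (alignment columns)
_PROMOTER = (0, 500)
_TSS_SEG1 = (500, 560)  # conserved TSS segment, deletable
_INS_POOL = (560, 632)  # 72 reference-gap columns for planted insertions
_TSS_SEG2 = (632, 652)
_TSS = (500, 652)
_UTR = (652, 680)
_CODING = (680, 860)  # 60 codons
_DONOR = 860
_WIDTH = 872

#: filler codons: no stop in frame 0
_SAFE_CODONS = ["GCC", "CTC", "GAC", "CAC", "AAC", "TCC", "GGA", "CAG", "TAC", "GAA"]


def region_template(seed: int = 7) -> tuple[RegionRow, FeatureAnnotation]:
    """Annotated reference region: promoter, TSS block (with an internal
    72-column insertion pool gapped in the reference), 5'UTR with a
    strong Kozak context, 60 coding codons starting ATG GCC ATG AAG
    (two in-frame starts and the AAG near-cognate three codons after
    ATG1), the GT donor and a short intronic tail."""
    rng = np.random.default_rng(seed)

    def bases(n: int) -> str:
        return "".join(rng.choice(BASES, size=n))

    promoter = bases(500)
    tss1 = bases(60)
    pool = GAP * 72
    tss2 = bases(20)
    utr = bases(22) + "GCCACC"
    codons = ["ATG", "GCC", "ATG", "AAG", "GAC"]
    codons += [rng.choice(_SAFE_CODONS) for _ in range(55)]
    coding = "".join(codons)
    donor = "GT"
    intron = bases(10)
    columns = promoter + tss1 + pool + tss2 + utr + coding + donor + intron
    assert len(columns) == _WIDTH
    ann = FeatureAnnotation(
        promoter_block=_PROMOTER,
        tss_block=_TSS,
        atg1_pos=_CODING[0],
        atg2_pos=_CODING[0] + 6,
        coding_block=_CODING,
        donor_pos=_DONOR,
    )
    ann.validate(_WIDTH)
    return RegionRow("reference", columns), ann


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted binary tree by sequential pair-joining; leaf labels
    sp01..spNN, internal labels n1..; reproducible under seed."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    frags = [f"sp{i + 1:02d}" for i in range(n_taxa)]
    k = 0
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        bl1, bl2 = rng.uniform(0.05, 0.25, size=2)
        k += 1
        merged = f"({frags[i]}:{bl1:.4f},{frags[j]}:{bl2:.4f})n{k}"
        frags = [f for idx, f in enumerate(frags) if idx not in (i, j)] + [merged]
    return dendropy.Tree.get(
        data=frags[0] + ";", schema="newick", preserve_underscores=True
    )


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def _protected_columns(ann: FeatureAnnotation) -> set[int]:
    cols = set(range(ann.atg1_pos, ann.atg1_pos + 3))
    cols |= set(range(ann.atg2_pos, ann.atg2_pos + 3))
    cols |= {ann.donor_pos, ann.donor_pos + 1}
    return cols


def evolve_region(
    template: RegionRow,
    ann: FeatureAnnotation,
    tree: dendropy.Tree,
    sub_rate: float,
    seed: int,
    protect: bool = True,
    extra_protected: set[int] | None = None,
) -> dict[str, str]:
    """Neutral point substitutions down the tree; columns preserved.

    With ``protect`` (default) the start codons and donor are immutable
    and coding substitutions that would create an in-frame stop are
    skipped, so background divergence never mimics a lesion.
    """
    rng = np.random.default_rng(seed)
    protected = _protected_columns(ann) if protect else set()
    if extra_protected:
        protected |= extra_protected
    width = len(template.columns)
    base_cols = np.array([c for c in range(width) if template.columns[c] != GAP])
    cstart, cend = ann.coding_block

    out: dict[str, str] = {}
    root = tree.seed_node
    root_seq = list(template.columns)
    seqs = {id(root): root_seq}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = seqs[id(node.parent_node)]
        blen = node.edge.length if node.edge.length is not None else 0.1
        p = -np.expm1(-sub_rate * blen)
        seq = list(parent_seq)
        if p > 0:
            hits = base_cols[rng.random(len(base_cols)) < p]
            for col in hits:
                col = int(col)
                if col in protected or seq[col] == GAP:
                    continue
                old = seq[col]
                new = str(rng.choice(BASES[BASES != old]))
                if protect and cstart <= col < cend:
                    codon_start = cstart + ((col - cstart) // 3) * 3
                    codon = "".join(
                        new if c == col else seq[c]
                        for c in range(codon_start, codon_start + 3)
                    )
                    if codon in STOP_CODONS:
                        continue
                seq[col] = new
        seqs[id(node)] = seq
        if node.is_leaf():
            out[_leaf_label(node)] = "".join(seq)
    return out


@dataclass(frozen=True)
class LesionSpec:
    """A branch-anchored lesion inherited by all descendant leaves.

    ``start`` is an alignment column (type-dependent anchor); ``length``
    an ungapped length in bp; ``seed`` fixes inserted bases so the whole
    clade carries an identical insertion.
    """

    branch: str
    ltype: LesionType
    start: int | None = None
    length: int = 0
    seed: int = 0


#: lesion-spec combinations sufficient for a loss verdict
_SUFFICIENT = frozenset(
    {
        LesionType.REGION_ABSENT,
        LesionType.DONOR_LOSS,
        LesionType.FRAMESHIFT_INDEL,
        LesionType.PREMATURE_STOP,
        LesionType.PROMOTER_DELETION,
        LesionType.PROMOTER_INSERTION,
    }
)


def _branch_sufficient(specs: list[LesionSpec]) -> bool:
    types = {s.ltype for s in specs}
    return bool(types & _SUFFICIENT) or {
        LesionType.START1_LOSS,
        LesionType.START2_LOSS,
    } <= types


@dataclass
class TruthTable:
    planted: dict[str, list[LesionSpec]]
    expected_calls: dict[str, str]
    expected_event_count: int


def _apply_lesion(seq: list[str], spec: LesionSpec, ann: FeatureAnnotation,
                  template: str) -> None:
    t = spec.ltype
    if t is LesionType.PROMOTER_DELETION:
        cols = [c for c in range(spec.start, _WIDTH) if template[c] != GAP]
        for c in cols[: spec.length]:
            seq[c] = GAP
    elif t is LesionType.PROMOTER_INSERTION:
        rng = np.random.default_rng(spec.seed)
        pool = list(range(*_INS_POOL))[: spec.length]
        ins = rng.choice(BASES, size=len(pool))
        for c, b in zip(pool, ins):
            seq[c] = str(b)
    elif t is LesionType.REGION_ABSENT:
        lo, hi = ann.region_span()
        for c in range(lo, hi):
            seq[c] = GAP
    elif t is LesionType.DONOR_LOSS:
        seq[ann.donor_pos + 1] = "C"  # GT -> GC
    elif t is LesionType.START1_LOSS:
        seq[ann.atg1_pos + 1] = "C"  # ATG -> ACG
    elif t is LesionType.START2_LOSS:
        seq[ann.atg2_pos + 2] = "A"  # ATG -> ATA
    elif t is LesionType.FRAMESHIFT_INDEL:
        for c in range(spec.start, spec.start + spec.length):
            seq[c] = GAP
    elif t is LesionType.PREMATURE_STOP:
        for c, b in zip(range(spec.start, spec.start + 3), "TGA"):
            seq[c] = b
    else:  # pragma: no cover
        raise ValueError(f"unsupported lesion type {t}")


def plant_lesions(
    rows: dict[str, str],
    tree: dendropy.Tree,
    specs: list[LesionSpec],
    ann: FeatureAnnotation,
    template: RegionRow,
) -> tuple[dict[str, str], TruthTable]:
    """Apply each lesion identically to every leaf under its branch.

    Loss-sufficient specs on nested branches are an input error (the
    truth table could not be exact); a non-sufficient spec (e.g. a lone
    start-codon mutation) may nest inside a lost clade, mirroring the
    mosaic degeneration that follows relaxation of constraint.
    """
    by_branch: dict[str, list[LesionSpec]] = {}
    for spec in specs:
        by_branch.setdefault(spec.branch, []).append(spec)

    nodes: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        label = _leaf_label(node) if node.is_leaf() else (node.label or "")
        if label:
            nodes[label] = node
    leaf_sets: dict[str, set[str]] = {}
    for branch in by_branch:
        if branch not in nodes:
            raise ValueError(f"lesion branch {branch!r} not in tree")
        leaf_sets[branch] = {_leaf_label(l) for l in nodes[branch].leaf_iter()}

    sufficient = {b for b, s in by_branch.items() if _branch_sufficient(s)}
    for a in sufficient:
        for b in sufficient:
            if a != b and leaf_sets[a] < leaf_sets[b]:
                raise ValueError(
                    f"loss-sufficient lesion branches nested: {a} inside {b}"
                )

    out = {label: list(seq) for label, seq in rows.items()}
    for branch, branch_specs in by_branch.items():
        for leaf in leaf_sets[branch]:
            if leaf not in out:
                continue
            for spec in branch_specs:
                _apply_lesion(out[leaf], spec, ann, template.columns)

    expected: dict[str, str] = {leaf: State.FUNCTIONAL.value for leaf in rows}
    for branch in sufficient:
        for leaf in leaf_sets[branch]:
            if leaf in expected:
                expected[leaf] = State.LOST.value
    n_events = sum(1 for b in sufficient if leaf_sets[b] & set(rows))
    truth = TruthTable(by_branch, expected, n_events)
    return {label: "".join(seq) for label, seq in out.items()}, truth


# --- read-count simulation -------------------------------------------------


def expected_counts(
    ratio_b_over_a: float, depth: float, model: ExonModel = ExonModel()
) -> tuple[float, float, float]:
    """Expected (reads_1A, reads_1B, reads_6) at a given B/A molar ratio.

    ``depth`` is the expected total first-exon read count; first-exon
    expectations are proportional to molar level x exon length, and the
    control exon's expected per-bp density is the mean of the two
    first-exon densities (the coherence convention exon 1A + 1B = exon 6
    is checked against).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if ratio_b_over_a < 0:
        raise ValueError("ratio must be >= 0")
    if np.isinf(ratio_b_over_a):
        w_a, w_b = 0.0, float(model.len_1b)
    else:
        w_a, w_b = float(model.len_1a), ratio_b_over_a * model.len_1b
    p_a = w_a / (w_a + w_b)
    e_1a = depth * p_a
    e_1b = depth * (1.0 - p_a)
    e_6 = model.len_6 * (e_1a / model.len_1a + e_1b / model.len_1b) / 2.0
    return e_1a, e_1b, e_6


def simulate_counts(
    ratio_b_over_a: float,
    depth: float,
    model: ExonModel = ExonModel(),
    dispersion: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int, int]:
    """Draw one library's (reads_1A, reads_1B, reads_6).

    Totals are Poisson at dispersion 0 and negative binomial
    (var = mu + dispersion*mu^2) otherwise; the first-exon total is
    split multinomially with probabilities proportional to molar level
    times exon length. Reproducible under seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    e_1a, e_1b, e_6 = expected_counts(ratio_b_over_a, depth, model)

    def draw_total(mu: float) -> int:
        if mu <= 0:
            return 0
        if dispersion <= 0:
            return int(rng.poisson(mu))
        r = 1.0 / dispersion
        return int(rng.negative_binomial(r, r / (r + mu)))

    n = draw_total(depth)
    p_a = e_1a / (e_1a + e_1b)
    reads_1a = int(rng.binomial(n, p_a)) if n else 0
    reads_1b = n - reads_1a
    reads_6 = draw_total(e_6)
    return reads_1a, reads_1b, reads_6


# --- loss-scenario generator ----------------------------------------------

#: the seven distinct loss archetypes; the premature stop sits upstream
#: (codon 8) of the frameshift (codon 15) so frameshift-induced stops can
#: never span-overlap a planted one
_ARCHETYPES = (
    "promoter_deletion",
    "promoter_insertion",
    "region_absent",
    "donor_loss",
    "frameshift_indel",
    "premature_stop",
    "double_atg",
)


def _archetype_specs(name: str, branch: str, seed: int) -> list[LesionSpec]:
    c0 = _CODING[0]
    if name == "promoter_deletion":
        return [LesionSpec(branch, LesionType.PROMOTER_DELETION, start=505, length=40)]
    if name == "promoter_insertion":
        return [LesionSpec(branch, LesionType.PROMOTER_INSERTION, length=36, seed=seed)]
    if name == "region_absent":
        return [LesionSpec(branch, LesionType.REGION_ABSENT)]
    if name == "donor_loss":
        return [LesionSpec(branch, LesionType.DONOR_LOSS)]
    if name == "frameshift_indel":
        return [LesionSpec(branch, LesionType.FRAMESHIFT_INDEL, start=c0 + 45, length=2)]
    if name == "premature_stop":
        return [LesionSpec(branch, LesionType.PREMATURE_STOP, start=c0 + 24)]
    if name == "double_atg":
        return [
            LesionSpec(branch, LesionType.START1_LOSS),
            LesionSpec(branch, LesionType.START2_LOSS),
        ]
    raise ValueError(name)


@dataclass
class LossScenario:
    tree: dendropy.Tree
    alignment: RegionAlignment
    truth: TruthTable


def simulate_loss_scenario(
    n_events: int,
    seed: int,
    n_taxa: int = 14,
    sub_rate: float = 0.05,
) -> LossScenario:
    """Plant 1-7 independent loss events with distinct lesion archetypes
    on disjoint (non-nested) branches of a random tree, with background
    divergence, and return the alignment with its exact truth table."""
    if not 1 <= n_events <= len(_ARCHETYPES):
        raise ValueError(f"n_events must be in 1..{len(_ARCHETYPES)}")
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, int(rng.integers(2**31 - 1)))
    template, ann = region_template()

    candidates = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(_leaf_label(l) for l in node.leaf_iter())
        if len(leaves) <= 3:
            label = _leaf_label(node) if node.is_leaf() else node.label
            candidates.append((label, leaves))
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, frozenset]] = []
    covered: set[str] = set()
    for idx in order:
        label, leaves = candidates[idx]
        if len(chosen) == n_events:
            break
        if leaves & covered:
            continue
        if len(covered | leaves) >= n_taxa:  # keep >= 1 functional leaf
            continue
        chosen.append((label, leaves))
        covered |= leaves
    if len(chosen) < n_events:
        return simulate_loss_scenario(n_events, seed + 1, n_taxa, sub_rate)

    archetypes = [_ARCHETYPES[i] for i in rng.permutation(len(_ARCHETYPES))[:n_events]]
    specs: list[LesionSpec] = []
    for name, (branch, _) in zip(archetypes, chosen):
        specs.extend(_archetype_specs(name, branch, seed=int(rng.integers(2**31 - 1))))

    rows = evolve_region(template, ann, tree, sub_rate, int(rng.integers(2**31 - 1)))
    rows, truth = plant_lesions(rows, tree, specs, ann, template)
    alignment = RegionAlignment(
        reference=template,
        rows=[RegionRow(label, seq) for label, seq in sorted(rows.items())],
        annotation=ann,
    )
    return LossScenario(tree, alignment, truth)


# --- the packaged species fixture ------------------------------------------

FIG2A_NEWICK = (
    "(Macropus:1,(Echinops:1,(((Erinaceus:1,Sorex:1)eulipotyphla:1,"
    "(Equus:1,(Vicugna:1,(Sus:1,Bos:1)suina:1)artiodactyla:1)ungulata:1"
    ")laurasiatheria:1,((Homo:1,Macaca:1)primates:1,(((Mus:1,Rattus:1)murinae:1,"
    "(Meriones:1,(Muroid_sp1:1,Muroid_sp2:1)unsampled_muroids:1)gerbils:1)muroidea:1,"
    "(Cavia:1,(Ctenomys:1,Octodon:1)octodontoidea:1)hystricomorpha:1)rodentia:1"
    ")euarchontoglires:1)boreoeutheria:1)placentalia:1)mammalia;"
)

#: species whose region is known only from low-coverage placeholders
_FIG2A_UNKNOWN = ("Muroid_sp1", "Muroid_sp2")


def _fig2a_specs() -> list[LesionSpec]:
    c0 = _CODING[0]
    return [
        # muroids: conserved TSS region deleted, replaced by a 72 bp insertion
        LesionSpec("muroidea", LesionType.PROMOTER_DELETION, start=500, length=60),
        LesionSpec("muroidea", LesionType.PROMOTER_INSERTION, length=72, seed=11),
        # mosaic coding degeneration after relaxation (not loss-sufficient alone)
        LesionSpec("Mus", LesionType.START1_LOSS),
        # independent coding lesions in the two octodontoid rodents
        LesionSpec("Ctenomys", LesionType.FRAMESHIFT_INDEL, start=c0 + 150, length=2),
        LesionSpec("Octodon", LesionType.PREMATURE_STOP, start=c0 + 60),
        # promoter deletion plus coding stop
        LesionSpec("Echinops", LesionType.PROMOTER_DELETION, start=510, length=40),
        LesionSpec("Echinops", LesionType.PREMATURE_STOP, start=c0 + 90),
        # whole region missing
        LesionSpec("Erinaceus", LesionType.REGION_ABSENT),
        # splice-donor losses on distant branches
        LesionSpec("Sus", LesionType.DONOR_LOSS),
        LesionSpec("Sorex", LesionType.DONOR_LOSS),
        # ATG2-only species (remain functional)
        LesionSpec("Equus", LesionType.START1_LOSS),
        LesionSpec("Vicugna", LesionType.START1_LOSS),
    ]


@dataclass
class Fig2aFixture:
    tree: dendropy.Tree
    alignment: RegionAlignment
    truth: TruthTable
    expected_independent_losses: int = 7
    expected_plain_dollo_events: int = 5


def make_fixture_fig2a(seed: int = 2015) -> Fig2aFixture:
    """The packaged transcription of the mammalian survey.

    Per-species states and lesion kinds follow the published survey
    text; the cladogram follows the figure. Unsampled muroid leaves are
    packaged as low-coverage placeholders (state unknown, wildcards for
    the Dollo mapping). Coding columns are excluded from background
    divergence so the attested lesion inventory is reproduced exactly;
    the seed only varies neutral promoter/UTR divergence and never the
    calls.
    """
    tree = dendropy.Tree.get(
        data=FIG2A_NEWICK, schema="newick", preserve_underscores=True
    )
    template, ann = region_template()
    rows = evolve_region(
        template,
        ann,
        tree,
        sub_rate=0.02,
        seed=seed,
        protect=True,
        extra_protected=set(range(*_CODING)) | {ann.donor_pos, ann.donor_pos + 1},
    )
    rows, truth = plant_lesions(rows, tree, _fig2a_specs(), ann, template)
    for sp in _FIG2A_UNKNOWN:
        truth.expected_calls[sp] = State.UNKNOWN.value
    region_rows = [
        RegionRow(label, seq, coverage_flag=label in _FIG2A_UNKNOWN)
        for label, seq in sorted(rows.items())
    ]
    alignment = RegionAlignment(reference=template, rows=region_rows, annotation=ann)
    return Fig2aFixture(tree=tree, alignment=alignment, truth=truth)


# --- reporter-construct archetypes ------------------------------------------


def fig2b_archetypes() -> list[Construct]:
    """The seven reporter archetypes mirrored from the translation assay.

    Synthetic stand-ins (the survey's sequences are not machine-readable):
    each is 5'UTR + exon-1A-like segment + reporter ORF. The exon segment
    carries ATG1, ATG2 two codons downstream, and the AAG near-cognate in
    strong context three codons downstream of ATG1; engineered ATG
    knockouts use two-substitution codons so they do not themselves
    create near-cognate sites. The reporter ORF contributes its own
    start plus one internal ATG (the downstream background sites).
    """
    utr = "CTCTTCCTCTCCCTTCTCTCCCGCCACC"  # no ATG, ends in strong context
    # exon codons: ATG1, GCC, ATG2, AAG, GAC + neutral fillers (no
    # near-cognates in frame 0, no stops)
    exon_codons = ["ATG", "GCC", "ATG", "AAG", "GAC"] + ["CAC", "CAA", "GAC", "TAC"] * 2
    reporter_codons = (
        ["ATG", "GCT", "TCC", "AAA", "GTT"]
        + ["TAC", "GAT", "CCA", "GAA", "CAT"]
        + ["ATG", "GAA", "TGG", "CCT", "GAC"]
        + ["GAT", "TCT", "GTC", "CAC", "TGA"]
    )

    def build(label: str, exon: list[str]) -> Construct:
        seq = utr + "".join(exon) + "".join(reporter_codons)
        return Construct(label, seq, reporter_start=len(utr) + 3 * len(exon))

    wt = list(exon_codons)
    atg1_mut = ["GCG"] + wt[1:]
    atg2_mut = wt[:2] + ["GCG"] + wt[3:]
    double_mut = ["GCG", "GCC", "GCG"] + wt[3:]
    cavia = wt[:5] + ["CAA", "CAC", "GAC", "TAC"] + wt[9:]
    equus = ["ACA"] + wt[1:]  # natural two-substitution loss of ATG1
    vicugna = ["GTA"] + wt[1:]
    return [
        build("homo_wt", wt),
        build("homo_atg1_mutant", atg1_mut),
        build("homo_atg2_mutant", atg2_mut),
        build("homo_double_mutant", double_mut),
        build("cavia", cavia),
        build("equus", equus),
        build("vicugna", vicugna),
    ]
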