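"""Nei genetic distance and neighbor-joining clustering.

Distances follow Nei's (1972) standard genetic distance

    D = -ln I,   I = Jxy / sqrt(Jx * Jy)

where Jxy, Jx and Jy are arithmetic means over shared loci of
``sum_i p_xi p_yi``, ``sum_i p_xi^2`` and ``sum_i p_yi^2``.  The unbiased
1978 variant (sample-size-corrected Jx, Jy) is available as an option.

The clustering units are *individual cultivars*: each inbred line's
"population frequencies" are its own equal-dose copy proportions (a fixed
diploid contributes frequency 1 to its single allele; a tetraploid scored
{A, B} contributes 0.5 / 0.5).  Grouped units (by subgroup label) pool the
whole sub-panel's frequencies instead.

Neighbor joining is the Saitou-Nei algorithm with the standard Q-criterion.
Tie-breaks are deterministic (lexicographically smallest pair of clade
representative labels) and negative branch-length estimates are clamped to
zero, so runs are bit-reproducible.  `skbio` containers (`DistanceMatrix`,
`TreeNode`) are used throughout, which gives Newick parsing and cophenetic
(tip-to-tip) distances for free.
"""
from __future__ import annotations

import io
import logging
import math
import re
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .diversity import AlleleFrequencySpectrum, allele_frequencies
from .panel_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

#: Replacement for an infinite distance (identity 0) between disjoint units.
DEFAULT_DISTANCE_CAP = 10.0

NEI_VARIANTS = ("1972", "1978")


# ---------------------------------------------------------------------------
# per-unit spectra
# ---------------------------------------------------------------------------

def individual_spectra(
    panel: GenotypePanel, individual_id: str
) -> dict[str, AlleleFrequencySpectrum]:
    """One individual's own equal-dose allele proportions, per scored locus."""
    i = panel.individual_index(individual_id)
    ind = panel.individuals[i]
    out: dict[str, AlleleFrequencySpectrum] = {}
    for marker, call in zip(panel.markers, panel.calls[i]):
        if call is MISSING:
            continue
        share = 1.0 / len(call)
        out[marker.name] = AlleleFrequencySpectrum(
            locus=marker.name,
            freqs={a: share for a in call},
            n_scored=1,
            n_copies=float(ind.ploidy),
            mode="copy",
        )
    return out


def group_spectra(
    panel: GenotypePanel, mode: str = "copy"
) -> dict[str, AlleleFrequencySpectrum]:
    """Pooled per-locus spectra of a (sub-)panel, skipping all-missing loci."""
    out: dict[str, AlleleFrequencySpectrum] = {}
    for marker in panel.markers:
        try:
            out[marker.name] = allele_frequencies(panel, marker.name, mode=mode)
        except Exception:
            continue
    return out


# ---------------------------------------------------------------------------
# Nei identity / distance
# ---------------------------------------------------------------------------

def nei_identity(
    spectra_x: Mapping[str, AlleleFrequencySpectrum],
    spectra_y: Mapping[str, AlleleFrequencySpectrum],
    variant: str = "1972",
) -> float:
    """Nei's normalized identity I over the loci scored in both units.

    Loci missing in either unit are excluded pairwise; with no shared locus
    a ``ValueError`` is raised.  Values marginally above 1 (rounding) are
    clamped to 1.
    """
    if variant not in NEI_VARIANTS:
        raise ValueError(f"variant must be one of {NEI_VARIANTS}, got {variant!r}")
    shared = sorted(set(spectra_x) & set(spectra_y))
    if not shared:
        raise ValueError("no locus scored in both units")
    jxy = jx = jy = 0.0
    for locus in shared:
        sx, sy = spectra_x[locus], spectra_y[locus]
        alleles = set(sx.freqs) | set(sy.freqs)
        jxy += sum(sx.freqs.get(a, 0.0) * sy.freqs.get(a, 0.0) for a in alleles)
        jx += _homozygosity(sx, variant)
        jy += _homozygosity(sy, variant)
    n = len(shared)
    jxy, jx, jy = jxy / n, jx / n, jy / n
    if jx <= 0 or jy <= 0:
        raise ValueError("degenerate within-unit identity")
    return min(1.0, jxy / math.sqrt(jx * jy))


def _homozygosity(spec: AlleleFrequencySpectrum, variant: str) -> float:
    j = float(np.sum(spec.p ** 2))
    if variant == "1978":
        c = spec.n_copies
        if c <= 1:
            raise ValueError(
                f"locus {spec.locus!r}: 1978 correction needs > 1 allele copy"
            )
        j = (c * j - 1.0) / (c - 1.0)
    return j


def nei_distance(
    spectra_x: Mapping[str, AlleleFrequencySpectrum],
    spectra_y: Mapping[str, AlleleFrequencySpectrum],
    variant: str = "1972",
    cap: float = DEFAULT_DISTANCE_CAP,
) -> float:
    """D = -ln I, capped at ``cap`` when the units share no alleles (I = 0)."""
    identity = nei_identity(spectra_x, spectra_y, variant=variant)
    if identity <= 0:
        logger.warning("identity 0: distance capped at %.3f", cap)
        return cap
    return min(cap, -math.log(identity))


def nei_distance_matrix(
    panel: GenotypePanel,
    unit: str = "individual",
    mode: str = "copy",
    variant: str = "1972",
    cap: float = DEFAULT_DISTANCE_CAP,
) -> DistanceMatrix:
    """Pairwise Nei distances between individuals or subgroup-pooled groups."""
    if unit == "individual":
        labels = panel.individual_ids
        spectra = [individual_spectra(panel, i) for i in labels]
    elif unit == "group":
        groups: dict[str, list[str]] = {}
        for ind in panel.individuals:
            if ind.subgroup is None:
                raise ValueError(f"individual {ind.id!r} has no subgroup label")
            groups.setdefault(ind.subgroup, []).append(ind.id)
        labels = sorted(groups)
        spectra = [group_spectra(panel.subset(groups[g]), mode=mode) for g in labels]
    else:
        raise ValueError(f"unit must be 'individual' or 'group', got {unit!r}")
    if len(labels) < 2:
        raise ValueError("need at least 2 units for a distance matrix")
    d = _pairwise_nei(spectra, variant=variant, cap=cap)
    return DistanceMatrix(d, ids=labels)


def _pairwise_nei(
    spectra: list[Mapping[str, AlleleFrequencySpectrum]], variant: str, cap: float
) -> np.ndarray:
    """Vectorized all-pairs Nei D; agrees with :func:`nei_distance` per pair."""
    all_loci = sorted(set().union(*spectra))
    n = len(spectra)
    n_loci = len(all_loci)
    scored = np.zeros((n, n_loci))
    j_self = np.zeros((n, n_loci))
    jxy = np.zeros((n, n))
    for col, locus in enumerate(all_loci):
        units = [i for i in range(n) if locus in spectra[i]]
        alleles = sorted(set().union(*(spectra[i][locus].freqs for i in units)))
        index = {a: k for k, a in enumerate(alleles)}
        freq = np.zeros((n, len(alleles)))
        for i in units:
            sp = spectra[i][locus]
            for a, p in sp.freqs.items():
                freq[i, index[a]] = p
            scored[i, col] = 1.0
            j_self[i, col] = _homozygosity(sp, variant)
        jxy += freq @ freq.T
    shared = scored @ scored.T
    off = ~np.eye(n, dtype=bool)
    if (shared[off] == 0).any():
        raise ValueError("some unit pair shares no scored locus")
    jx = (scored * j_self) @ scored.T  # (i, j): sum of unit i's homozygosity over shared loci
    with np.errstate(divide="ignore", invalid="ignore"):
        identity = np.minimum(1.0, jxy / np.sqrt(jx * jx.T))
        d = np.where(identity > 0, -np.log(np.maximum(identity, 1e-300)), cap)
    n_capped = int((d[off] >= cap).sum())
    if n_capped:
        logger.warning("%d pair distance(s) capped at %.3f", n_capped // 2, cap)
    d = np.minimum(d, cap)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry against float noise


# ---------------------------------------------------------------------------
# band-similarity backend (Dice / Jaccard on allele presence)
# ---------------------------------------------------------------------------

def band_distance_matrix(panel: GenotypePanel, method: str = "dice") -> DistanceMatrix:
    """1 - similarity on band (allele) presence, an NTSYS-style alternative.

    Loci missing in either individual of a pair are ignored pairwise.
    """
    if method not in ("dice", "jaccard"):
        raise ValueError(f"method must be 'dice' or 'jaccard', got {method!r}")
    labels = panel.individual_ids
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a_total = b_total = shared = union = 0
            for col in range(len(panel.markers)):
                ca, cb = panel.calls[i][col], panel.calls[j][col]
                if ca is MISSING or cb is MISSING:
                    continue
                a_total += len(ca)
                b_total += len(cb)
                shared += len(ca & cb)
                union += len(ca | cb)
            if union == 0:
                raise ValueError(
                    f"no locus scored in both {labels[i]!r} and {labels[j]!r}"
                )
            if method == "dice":
                sim = 2.0 * shared / (a_total + b_total)
            else:
                sim = shared / union
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree as a `TreeNode` whose root is the final
    trifurcation (binary internal nodes elsewhere).  Among pairs tying on
    the Q-criterion the join with the lexicographically smallest pair of
    clade representative labels (the smallest leaf label in each clade) is
    taken.  Negative branch-length estimates are clamped to 0 with the
    pre-clamp value logged.
    """
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    nodes = [TreeNode(name=label) for label in dm.ids]
    reps = list(dm.ids)  # representative (smallest) leaf label per clade
    d = d.copy()

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = _clamp_length(li, reps[i])
        nodes[j].length = _clamp_length(lj, reps[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_next = np.zeros((r - 1, r - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final trifurcation via the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp_length((dab + dac - dbc) / 2.0, reps[0])
    b.length = _clamp_length((dab + dbc - dac) / 2.0, reps[1])
    c.length = _clamp_length((dac + dbc - dab) / 2.0, reps[2])
    return TreeNode(children=[a, b, c])


def _clamp_length(length: float, label: str) -> float:
    if length < 0:
        logger.info("clamping negative branch length %.6g at %s to 0", length, label)
        return 0.0
    return float(length)


# ---------------------------------------------------------------------------
# Newick / cophenetic
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,']")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Standard Newick string with branch lengths at the given precision.

    Labels containing whitespace or Newick syntax characters are quoted.
    """

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = _newick_label(node.name)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + _newick_label(
                node.name
            )
        if node.length is not None:
            body += f":{node.length:.{precision}f}"
        return body

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length (tip-to-tip) distance between every leaf pair."""
    return tree.tip_tip_distances()


def subtree_leaf_sets(tree: TreeNode) -> set[frozenset]:
    """Leaf-label sets of every internal edge; a topology fingerprint.

    For unrooted comparison each edge's bipartition is normalized to the
    side not containing the overall smallest label.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True when two unrooted trees induce identical bipartitions."""
    return subtree_leaf_sets(t1) == subtree_leaf_sets(t2)
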