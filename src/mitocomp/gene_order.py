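"""Circular gene orders, pattern grouping, and rearrangement inference.

A gene order is one circuit of the circular genome as a list of signed
tokens (``-tok`` marks the minus strand).  Two genomes share a gene-order
*pattern* iff their orders are identical after canonicalization (rotation to
a fixed anchor, reflection normalized).  The difference between two orders
is explained as deletions, insertions, inversions, and a minimal set of
translocated genes relative to a maximum common circular subsequence — the
descriptive level at which tRNA rearrangements are reported in comparative
mitogenomics, not a rearrangement edit distance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

ANCHORS = ("cox1", "cob", "rrnL")


def _sign_split(tok: str) -> tuple[str, int]:
    return (tok[1:], -1) if tok.startswith("-") else (tok, 1)


@dataclass(frozen=True)
class GeneOrder:
    """An ordered circuit of signed gene tokens."""

    tokens: tuple
    include_cr: bool = True

    def __post_init__(self):
        names = [(_sign_split(t)[0]) for t in self.tokens]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tokens in gene order: {dup} "
                             "(suffix duplicates with _2)")

    @property
    def names(self) -> tuple:
        return tuple(_sign_split(t)[0] for t in self.tokens)

    def without_cr(self) -> "GeneOrder":
        return GeneOrder(tuple(t for t in self.tokens
                               if _sign_split(t)[0] != "CR"), include_cr=False)

    def __len__(self):
        return len(self.tokens)


def extract_order(g, include_cr: bool = True) -> GeneOrder:
    """Gene order of an annotated genome: tokens by ascending start, signed
    by strand."""
    toks = []
    for f in sorted(g.features, key=lambda f: f.start):
        if not include_cr and f.feature_class == "CR":
            continue
        toks.append(f.token if f.strand == "+" else "-" + f.token)
    return GeneOrder(tuple(toks), include_cr=include_cr)


def _flip(tok: str) -> str:
    return tok[1:] if tok.startswith("-") else "-" + tok


def canonicalize(o: GeneOrder) -> GeneOrder:
    """Rotate to the anchor gene; reflect first if the anchor is on '-'.

    The canonical form is invariant to rotation of the circle and to reading
    it from the complementary strand, so canonical equality is pattern
    identity.  Anchors are tried in order cox1, cob, rrnL.
    """
    toks = list(o.tokens)
    names = [(_sign_split(t)[0]) for t in toks]
    anchor = next((a for a in ANCHORS if a in names), None)
    if anchor is None:
        raise ValueError(f"no anchor gene found (tried {', '.join(ANCHORS)})")
    i = names.index(anchor)
    if toks[i].startswith("-"):
        toks = [_flip(t) for t in reversed(toks)]
        names = [(_sign_split(t)[0]) for t in toks]
        i = names.index(anchor)
    toks = toks[i:] + toks[:i]
    return GeneOrder(tuple(toks), include_cr=o.include_cr)


@dataclass
class PatternCatalog:
    """Pattern label -> canonical order, and genome -> pattern label."""

    patterns: dict = field(default_factory=dict)        # label -> GeneOrder
    assignments: dict = field(default_factory=dict)     # genome_id -> label

    def members(self, label: str) -> list:
        return sorted(g for g, l in self.assignments.items() if l == label)


def _label(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def group_patterns(orders: dict) -> PatternCatalog:
    """Group genomes by identical canonical gene order.

    Labels are assigned A, B, C ... by descending group size; ties are broken
    by the lexicographically earliest genome id in the group, so the catalog
    is deterministic for a given input set.
    """
    groups: dict[tuple, list[str]] = {}
    canon: dict[tuple, GeneOrder] = {}
    for gid, order in orders.items():
        c = canonicalize(order)
        groups.setdefault(c.tokens, []).append(gid)
        canon[c.tokens] = c
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    cat = PatternCatalog()
    for i, (key, gids) in enumerate(ranked):
        label = _label(i)
        cat.patterns[label] = canon[key]
        for gid in gids:
            cat.assignments[gid] = label
    return cat


@dataclass(frozen=True)
class RearrangementEvent:
    """One inferred event between two gene orders.

    ``old_neighbors``/``new_neighbors`` are the (left, right) tokens flanking
    the gene in the reference / alternate order: a deletion carries only old
    neighbors, an insertion only new ones, a translocation both.
    """

    kind: str  # deletion | insertion | translocation | inversion
    token: str
    old_neighbors: tuple | None = None
    new_neighbors: tuple | None = None


@dataclass
class RearrangementReport:
    events: list
    moved_set_size: int

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]


def _neighbors(names: tuple, name: str) -> tuple:
    i = names.index(name)
    return names[i - 1], names[(i + 1) % len(names)]


def _lcs_keep(a: list, b: list) -> set:
    """Tokens of one maximum common subsequence of two lists of uniques."""
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(lb - 1, -1, -1):
            row[j] = nxt[j + 1] + 1 if a[i] == b[j] else max(nxt[j], row[j + 1])
    keep = set()
    i = j = 0
    while i < la and j < lb:
        if a[i] == b[j]:
            keep.add(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def _max_common_circular_subsequence(a: tuple, b: tuple) -> set:
    """Largest token set kept in cyclic order by both circular permutations.

    Any common cyclic subsequence can be linearized at one of its own
    elements, so rotating both circles to each shared token and taking the
    ordinary LCS explores every candidate.
    """
    shared = [t for t in a if t in set(b)]
    best: set = set()
    bset = set(a) & set(b)
    a_s = [t for t in a if t in bset]
    b_s = [t for t in b if t in bset]
    for t in shared:
        ia, ib = a_s.index(t), b_s.index(t)
        ra = a_s[ia:] + a_s[:ia]
        rb = b_s[ib:] + b_s[:ib]
        keep = _lcs_keep(ra, rb)
        if len(keep) > len(best):
            best = keep
    return best


def diff_orders(ref: GeneOrder, alt: GeneOrder) -> RearrangementReport:
    """Explain ``alt`` relative to ``ref`` as deletions, insertions,
    inversions and a minimal translocated set.

    Tokens present only in ``ref`` are deletions; only in ``alt``,
    insertions.  Shared tokens outside a maximum common circular subsequence
    are translocations (the moved set is minimal within the common-
    subsequence model).  Sign mismatches of shared tokens are inversions.
    Events are ordered so that :func:`apply_events` replays them onto ``ref``
    to give ``alt``.
    """
    ref = canonicalize(ref)
    alt = canonicalize(alt)
    rn, an = ref.names, alt.names
    rset, aset = set(rn), set(an)

    events: list[RearrangementEvent] = []
    for name in rn:
        if name not in aset:
            events.append(RearrangementEvent(
                "deletion", name, old_neighbors=_neighbors(rn, name)))

    keep = _max_common_circular_subsequence(rn, an)
    moved = [n for n in an if n in rset and n not in keep]
    for name in moved:  # in alt scan order, so replay can resolve neighbors
        events.append(RearrangementEvent(
            "translocation", name,
            old_neighbors=_neighbors(rn, name),
            new_neighbors=_neighbors(an, name)))
    for name in an:
        if name not in rset:
            events.append(RearrangementEvent(
                "insertion", name, new_neighbors=_neighbors(an, name)))

    ref_sign = {(_sign_split(t)[0]): _sign_split(t)[1] for t in ref.tokens}
    alt_sign = {(_sign_split(t)[0]): _sign_split(t)[1] for t in alt.tokens}
    for name in an:
        if name in rset and ref_sign[name] != alt_sign[name]:
            events.append(RearrangementEvent("inversion", name))

    return RearrangementReport(events, moved_set_size=len(moved))


def apply_events(o: GeneOrder, events) -> GeneOrder:
    """Replay rearrangement events onto an order.

    Placement of an inserted or translocated token uses its new neighbors:
    after the left one when present, else before the right one; if neither
    neighbor exists in the current order the event is unresolvable.
    """
    toks = list(canonicalize(o).tokens)

    def names() -> list:
        return [_sign_split(t)[0] for t in toks]

    for e in events:
        ns = names()
        if e.kind == "deletion":
            if e.token not in ns:
                raise ValueError(f"cannot delete absent token {e.token}")
            del toks[ns.index(e.token)]
        elif e.kind == "inversion":
            i = ns.index(e.token)
            toks[i] = _flip(toks[i])
        elif e.kind in ("insertion", "translocation"):
            signed = e.token
            if e.kind == "translocation":
                i = ns.index(e.token)
                signed = toks[i]
                del toks[i]
                ns = names()
            left, right = e.new_neighbors
            if left in ns:
                toks.insert(ns.index(left) + 1, signed)
            elif right in ns:
                toks.insert(ns.index(right), signed)
            else:
                raise ValueError(
                    f"neither new neighbor ({left}, {right}) of {e.token} "
                    "is present in the current order")
        else:
            raise ValueError(f"unknown event kind {e.kind!r}")
    return canonicalize(GeneOrder(tuple(toks), include_cr=o.include_cr))


def same_pattern(a: GeneOrder, b: GeneOrder) -> bool:
    return canonicalize(a).tokens == canonicalize(b).tokens


# ---------------------------------------------------------------- order files

def read_order_file(path: str | os.PathLike) -> dict:
    """One genome per line: ``genome_id: tok1 tok2 ...`` (``-tok`` = minus)."""
    orders = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, _, rest = line.partition(":")
            orders[gid.strip()] = GeneOrder(tuple(rest.split()))
    return orders


def write_order_file(orders: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gid, order in orders.items():
            fh.write(f"{gid}: " + " ".join(order.tokens) + "\n")


def write_catalog(cat: PatternCatalog, path: str | os.PathLike) -> None:
    """TSV of genome -> pattern label, then one line per pattern's order."""
    with open(path, "w") as fh:
        fh.write("genome_id\tpattern\n")
        for gid in sorted(cat.assignments):
            fh.write(f"{gid}\t{cat.assignments[gid]}\n")
        for label in sorted(cat.patterns):
            fh.write(f"#pattern {label}: "
                     + " ".join(cat.patterns[label].tokens) + "\n")
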