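"""tRNA secondary-structure validation: dot-bracket parsing, cloverleaf
partitioning, and atypical-arm reporting.

The module validates *given* structures (e.g. annotation-pipeline
predictions) rather than folding sequences: the canonical cloverleaf is an
acceptor stem closing a multiloop from which three helices branch — the
dihydrouridine (DHU) arm, the anticodon arm and the TΨC arm, in 5'→3' order.
Metazoan mitochondrial tRNAs frequently truncate the DHU arm; a stem with a
single complementary base pair (or none) is flagged atypical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass


@dataclass(frozen=True)
class Helix:
    """A maximal stack of directly nested base pairs.

    ``pairs`` is a list of 1-based (i, j) with i < j, ordered outermost
    first: (i, j), (i+1, j-1), ...
    """

    pairs: tuple

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def outer(self) -> tuple:
        return self.pairs[0]

    @property
    def inner(self) -> tuple:
        return self.pairs[-1]


@dataclass(frozen=True)
class PairedStructure:
    sequence: str
    pairs: frozenset  # of (i, j), 1-based, i < j

    def to_dot_bracket(self) -> str:
        db = ["."] * len(self.sequence)
        for i, j in self.pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        return "".join(db)

    def helices(self) -> list:
        """Maximal stacks of directly nested pairs, by outer opening position."""
        pairs = sorted(self.pairs)
        pairset = set(pairs)
        out = []
        for i, j in pairs:
            if (i - 1, j + 1) in pairset:
                continue  # not the outermost pair of its stack
            stack = [(i, j)]
            while (stack[-1][0] + 1, stack[-1][1] - 1) in pairset:
                stack.append((stack[-1][0] + 1, stack[-1][1] - 1))
            out.append(Helix(tuple(stack)))
        return out


def parse_dot_bracket(seq: str, db: str) -> PairedStructure:
    """Stack-match a dot-bracket string (one bracket level; nested only)."""
    if len(seq) != len(db):
        raise ValueError(f"sequence length {len(seq)} != structure length {len(db)}")
    bad = set(db) - set("().")
    if bad:
        raise ValueError(f"unsupported structure symbols: {sorted(bad)}")
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return PairedStructure(seq.upper().replace("U", "T"), frozenset(pairs))


@dataclass(frozen=True)
class Arm:
    helix: Helix
    loop: tuple  # (first, last) loop positions, 1-based inclusive

    @property
    def n_pairs(self) -> int:
        return self.helix.n_pairs

    @property
    def loop_len(self) -> int:
        return self.loop[1] - self.loop[0] + 1


@dataclass(frozen=True)
class Cloverleaf:
    sequence: str
    acceptor_stem: Helix
    dhu_arm: Arm | None
    anticodon_arm: Arm | None
    tpsic_arm: Arm | None
    anticodon: str | None


def _arm_from_helix(seq: str, h: Helix) -> Arm:
    i, j = h.inner
    return Arm(h, (i + 1, j - 1))


def partition_cloverleaf(ps: PairedStructure) -> Cloverleaf:
    """Assign the helices of a nested structure to the cloverleaf arms.

    The acceptor stem is the helix whose outer pair encloses all others; the
    helices branching from its multiloop are assigned in 5'→3' order to DHU,
    anticodon and TΨC arms.  When only two branch helices are present the
    DHU arm is taken as the missing one (the arm mitochondrial tRNAs lose);
    a single branch helix is read as the anticodon arm.
    """
    helices = ps.helices()
    if not helices:
        raise ValueError("not a cloverleaf: no helices at all")
    helices.sort(key=lambda h: h.outer[0])
    acceptor = helices[0]
    ai, aj = acceptor.inner
    branches = [h for h in helices[1:] if ai < h.outer[0] and h.outer[1] < aj]
    if len(helices) > 1 and not branches:
        raise ValueError("not a cloverleaf: no exterior helix closing a multiloop")

    dhu = anticodon = tpsic = None
    arms = [_arm_from_helix(ps.sequence, h) for h in branches[:3]]
    if len(arms) >= 3:
        dhu, anticodon, tpsic = arms[0], arms[1], arms[2]
    elif len(arms) == 2:
        anticodon, tpsic = arms
    elif len(arms) == 1:
        anticodon = arms[0]

    ac = None
    if anticodon is not None and anticodon.loop_len >= 5:
        lo, hi = anticodon.loop
        mid = (lo + hi) // 2
        ac = ps.sequence[mid - 2:mid + 1]
    return Cloverleaf(ps.sequence, acceptor, dhu, anticodon, tpsic, ac)


DEFAULT_THRESHOLDS = {
    "acceptor_min_pairs": 6,
    "arm_min_pairs": 2,
    "anticodon_loop_min": 5,
}


def arm_report(cl: Cloverleaf, thresholds: dict | None = None) -> dict:
    """Per-arm pair counts plus a typicality verdict.

    A cloverleaf is typical iff the acceptor stem has at least 6 pairs, all
    three arms are present with at least 2 pairs each, and the anticodon
    loop has at least 5 nt.  A 1-pair DHU stem — the hallmark anomaly of
    some mitochondrial serine tRNAs — is therefore atypical.
    """
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    report = {
        "acceptor_pairs": cl.acceptor_stem.n_pairs,
        "dhu_pairs": cl.dhu_arm.n_pairs if cl.dhu_arm else 0,
        "anticodon_pairs": cl.anticodon_arm.n_pairs if cl.anticodon_arm else 0,
        "tpsic_pairs": cl.tpsic_arm.n_pairs if cl.tpsic_arm else 0,
        "anticodon_loop_len": cl.anticodon_arm.loop_len if cl.anticodon_arm else 0,
        "anticodon": cl.anticodon,
    }
    reasons = []
    if report["acceptor_pairs"] < th["acceptor_min_pairs"]:
        reasons.append(f"acceptor_pairs={report['acceptor_pairs']} < "
                       f"{th['acceptor_min_pairs']}")
    for arm in ("dhu", "anticodon", "tpsic"):
        if report[f"{arm}_pairs"] < th["arm_min_pairs"]:
            reasons.append(f"{arm}_pairs={report[f'{arm}_pairs']} < "
                           f"{th['arm_min_pairs']}")
    if report["anticodon_loop_len"] < th["anticodon_loop_min"]:
        reasons.append(f"anticodon_loop_len={report['anticodon_loop_len']} < "
                       f"{th['anticodon_loop_min']}")
    report["typical"] = not reasons
    report["reasons"] = reasons
    return report


def read_structure_file(path: str | os.PathLike) -> dict:
    """Read 3-line records (``>id`` / sequence / dot-bracket) into
    {id: PairedStructure}."""
    out = {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>id' line, got {lines[i]!r}")
        rid = lines[i][1:].split()[0]
        out[rid] = parse_dot_bracket(lines[i + 1], lines[i + 2])
        i += 3
    return out
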