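"""Brute-force reference implementations used as cross-checks.

These are deliberately simple, exhaustively-scanning re-implementations of
the contracts the optimized code paths promise: every diagonal of the
alignment matrix is visited without seeding, and clustering is replayed
from a full pairwise predicate matrix. They exist to validate the fast
paths on small inputs and are not meant for production-size data.
"""

from __future__ import annotations

from .align import AlignParams, karlin_altschul_evalue
from .model import revcomp

HspTuple = tuple[int, int, int, int, str, int, int]  # qs, qe, ss, se, strand, score, ident


def _reference_segments(
    steps: list[int], xdrop: int
) -> list[tuple[int, int, int]]:
    """Maximal X-drop segments by direct restart-scanning (no numpy)."""
    segs = []
    st = 0
    n = len(steps)
    while st < n:
        s = 0
        best = 0
        best_end = st
        cut = None
        t = st
        while t < n:
            s += steps[t]
            if s > best:
                best, best_end = s, t + 1
            if s <= 0 or best - s > xdrop:
                cut = t
                break
            t += 1
        if best > 0:
            segs.append((st, best_end, best))
        st = cut + 1 if cut is not None else n
    return segs


def exhaustive_hsps(query: str, subject: str, params: AlignParams) -> set[HspTuple]:
    """All maximal ungapped segments by scanning every diagonal.

    Applies the same scoring, X-drop, N-break, seed-run and E-value rules
    as the seeded aligner, but without any seeding shortcut. Coordinates
    follow the aligner's convention: subject interval on its plus strand,
    ``strand`` giving the subject orientation.
    """
    out: set[HspTuple] = set()
    strands = ["+"] if params.strand == "plus" else ["+", "-"]
    for strand in strands:
        sub = subject if strand == "+" else revcomp(subject)
        for diag in range(-(len(query) - 1), len(sub)):
            qlo = max(0, -diag)
            qhi = min(len(query), len(sub) - diag)
            if qhi - qlo < params.word_size:
                continue
            steps = []
            nflags = []
            for t in range(qlo, qhi):
                qc, sc = query[t], sub[t + diag]
                if qc == "N" or sc == "N":
                    nflags.append(True)
                    steps.append(0)
                else:
                    nflags.append(False)
                    steps.append(params.match if qc == sc else params.mismatch)
            # honour N hard breaks by splitting the diagonal
            chunk_start = 0
            pieces = []
            for i, brk in enumerate(nflags):
                if brk:
                    pieces.append((chunk_start, i))
                    chunk_start = i + 1
            pieces.append((chunk_start, len(steps)))
            for cs, ce in pieces:
                for st, en, score in _reference_segments(steps[cs:ce], params.xdrop):
                    a, b = cs + st, cs + en
                    if b - a < params.word_size:
                        continue
                    run = best_run = 0
                    for t in range(a, b):
                        run = run + 1 if steps[t] == params.match else 0
                        best_run = max(best_run, run)
                    if best_run < params.word_size:
                        continue
                    ev = karlin_altschul_evalue(
                        score, len(query), len(subject), params.match, params.mismatch
                    )
                    if ev > params.evalue_max:
                        continue
                    ident = sum(1 for t in range(a, b) if steps[t] == params.match)
                    qs, qe = qlo + a, qlo + b
                    ss = qlo + diag + a
                    se = ss + (qe - qs)
                    if strand == "-":
                        ss, se = len(subject) - se, len(subject) - ss
                    out.add((qs, qe, ss, se, strand, score, ident))
    return out


def hsp_tuples(hsps) -> set[HspTuple]:
    """Canonical tuples of aligner HSPs for set comparison with the oracle."""
    return {
        (h.mac.start, h.mac.end, h.mic.start, h.mic.end, h.strand, h.score, h.identities)
        for h in hsps
    }


def bruteforce_greedy_clusters(
    seqs: dict[str, str], predicate
) -> dict[str, list[str]]:
    """Longest-first greedy clustering replayed from a full pairwise matrix.

    ``predicate(shorter, longer)`` decides membership. Returns
    representative -> members (members exclude the representative). Ties on
    length break lexicographically by id for determinism.
    """
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    matrix = {}
    for a in order:
        for b in order:
            if a == b:
                continue
            sa, sb = seqs[a], seqs[b]
            shorter, longer = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            matrix[(a, b)] = predicate(shorter, longer)
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        home = None
        for rep in reps:
            if matrix[(sid, rep)]:
                home = rep
                break
        if home is None:
            reps.append(sid)
            clusters[sid] = []
        else:
            clusters[home].append(sid)
    return clusters


def bruteforce_transitive_clusters(
    seqs: dict[str, str], predicate
) -> list[set[str]]:
    """Connected components of the pairwise-similarity graph."""
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sa, sb = seqs[a], seqs[b]
            shorter, longer = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            if predicate(shorter, longer):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=lambda s: sorted(s)[0])
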