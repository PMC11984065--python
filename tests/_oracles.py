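"""Independent brute-force oracles used to validate the fast implementations.

These enumerate exhaustively and apply the documented rules directly; they
share no code with the package's matching/merging implementations.
"""

from __future__ import annotations


def brute_force_match(s1, s2, window, unique_responses=False, gaps_only=False):
    """Exhaustive pair enumeration + predicate + argmin turn matcher.

    Returns sorted (s1_index, s2_index, transition) triples under the same
    documented rules as ``match_turns``: candidates are responder onsets in
    ``(v.onset, v.offset + window]`` (lower bound ``v.offset`` when
    gaps-only); nearest by |transition| with gaps beating overlaps on exact
    magnitude ties, then earlier responder onsets; one-to-one assignment is
    greedy by ascending |transition| with earlier initiators winning ties.
    """
    candidates = []
    for i, v in enumerate(s1):
        lower = v.offset if gaps_only else v.onset
        for j, u in enumerate(s2):
            if u.onset > lower and u.onset <= v.offset + window:
                candidates.append((i, j, u.onset - v.offset))

    picked = []
    if not unique_responses:
        for i in range(len(s1)):
            mine = [c for c in candidates if c[0] == i]
            if mine:
                picked.append(
                    min(mine, key=lambda c: (abs(c[2]), c[2] < 0, s2[c[1]].onset))
                )
    else:
        order = sorted(
            candidates,
            key=lambda c: (abs(c[2]), s1[c[0]].onset, c[2] < 0, s2[c[1]].onset),
        )
        used1, used2 = set(), set()
        for i, j, t in order:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            picked.append((i, j, t))
    return sorted(picked)


def brute_force_merge(utterances, max_pause, merge_across_categories=False):
    """Repeated single-pass fuser: fuse the first eligible pair until fixpoint."""
    utts = [[u.onset, u.offset, u.category] for u in utterances]
    changed = True
    while changed:
        changed = False
        for k in range(len(utts) - 1):
            a, b = utts[k], utts[k + 1]
            same = merge_across_categories or a[2] == b[2]
            if same and (b[0] - a[1]) <= max_pause + 1e-9:
                utts[k] = [a[0], max(a[1], b[1]), a[2]]
                del utts[k + 1]
                changed = True
                break
    return [(a, b, c) for a, b, c in utts]
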