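"""Independent brute-force reference implementations.

Every function here is a deliberately naive per-site / double-loop
re-derivation of a package statistic, kept free of any package internals so
the two routes can disagree. Used by the oracle-equivalence tests.
"""

from __future__ import annotations

MISSING = set("N-")
AMBIGUITY = set("RYSWKMBDHV")


def masked(res: str, policy) -> bool:
    if res in MISSING:
        return True
    return policy.ambiguity == "treat_as_missing" and res in AMBIGUITY


def complete_deletion_keep(seqs: list[str], policy) -> list[bool]:
    """Sites unmasked in every sequence."""
    length = len(seqs[0])
    return [
        all(not masked(s[i], policy) for s in seqs) for i in range(length)
    ]


def bf_p_distance(
    a: str, b: str, policy, keep: list[bool] | None = None
) -> tuple[int, int]:
    """(differing, compared) by a per-site loop."""
    diff = comp = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if keep is not None and not keep[i]:
            continue
        if masked(x, policy) or masked(y, policy):
            continue
        comp += 1
        if x != y or x in AMBIGUITY or y in AMBIGUITY:
            diff += 1
    return diff, comp


def bf_distance_matrix(records: dict[str, str], policy) -> dict:
    ids = list(records)
    keep = None
    if policy.mode == "complete_deletion":
        keep = complete_deletion_keep(list(records.values()), policy)
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out[(a, b)] = bf_p_distance(records[a], records[b], policy, keep)
    return out


def bf_fixed_substitutions(
    records: dict[str, str],
    members_a: list[str],
    members_b: list[str],
    policy,
) -> tuple[list[tuple[int, str, str]], int]:
    """(diagnostic sites, evaluated sites) by per-site set comparison."""
    seqs_a = [records[s] for s in members_a]
    seqs_b = [records[s] for s in members_b]
    keep = None
    if policy.mode == "complete_deletion":
        keep = complete_deletion_keep(seqs_a + seqs_b, policy)
    length = len(seqs_a[0])
    sites, evaluated = [], 0
    for i in range(length):
        if keep is not None and not keep[i]:
            continue
        states_a = {s[i] for s in seqs_a if not masked(s[i], policy)}
        states_b = {s[i] for s in seqs_b if not masked(s[i], policy)}
        if not states_a or not states_b:
            continue
        evaluated += 1
        if len(states_a) == 1 and len(states_b) == 1:
            sa, sb = next(iter(states_a)), next(iter(states_b))
            if sa in AMBIGUITY or sb in AMBIGUITY:
                continue
            if sa != sb:
                sites.append((i + 1, sa, sb))
    return sites, evaluated


def bf_min_intergroup(distances: dict, members_a, members_b):
    """Minimal (diff/comp) over inter-group pairs; returns (pair, p)."""
    best = None
    for sa in members_a:
        for sb in members_b:
            diff, comp = distances.get((sa, sb), distances.get((sb, sa)))
            p = diff / comp
            if best is None or p < best[1]:
                best = ((sa, sb), p)
    return best


def bf_components(ids: list[str], distances: dict, threshold: float) -> list[set]:
    """Connected components via naive repeated expansion."""
    adjacency = {sid: set() for sid in ids}
    for (a, b), (diff, comp) in distances.items():
        if diff / comp <= threshold:
            adjacency[a].add(b)
            adjacency[b].add(a)
    unseen = set(ids)
    components = []
    while unseen:
        frontier = {unseen.pop()}
        comp = set()
        while frontier:
            node = frontier.pop()
            comp.add(node)
            for nb in adjacency[node]:
                if nb not in comp:
                    frontier.add(nb)
        unseen -= comp
        components.append(comp)
    return components


def random_alignment(rng, n_max=12, length_max=100, mask_prob=0.08):
    """A random ragged-free test alignment with gaps and ambiguities."""
    n = int(rng.integers(2, n_max + 1))
    length = int(rng.integers(4, length_max + 1))
    alphabet = list("ACGT")
    noise = list("N-RY")
    records = {}
    for i in range(n):
        seq = []
        for _ in range(length):
            if rng.random() < mask_prob:
                seq.append(noise[int(rng.integers(len(noise)))])
            else:
                seq.append(alphabet[int(rng.integers(4))])
        records[f"s{i:02d}"] = "".join(seq)
    return records
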