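"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

import itertools

import numpy as np

from pbinkit.pbin import BipartiteNetwork, ModulePartition, barber_modularity


def enumerate_set_partitions(items):
    """All set partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in enumerate_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity_bruteforce(network: BipartiteNetwork) -> float:
    """Exhaustive maximum of Barber's Q over all joint node partitions."""
    nodes = network.row_labels + network.col_labels
    best = -np.inf
    for part in enumerate_set_partitions(nodes):
        modules = {}
        for mid, block in enumerate(part, start=1):
            for node in block:
                modules[node] = mid
        p = ModulePartition(
            {r: modules[r] for r in network.row_labels},
            {c: modules[c] for c in network.col_labels},
            q=0.0,
        )
        best = max(best, barber_modularity(network, p))
    return float(best)


def nodf_bruteforce(matrix: np.ndarray) -> float:
    """Independent pair-enumeration NODF oracle (python loops, sets)."""
    A = np.asarray(matrix)
    R, C = A.shape
    total = 0.0
    for axis_mat, n in ((A, R), (A.T, C)):
        fills = [set(np.flatnonzero(row)) for row in axis_mat]
        for i, j in itertools.permutations(range(n), 2):
            ki, kj = len(fills[i]), len(fills[j])
            if ki > kj > 0:
                total += 100.0 * len(fills[i] & fills[j]) / kj
    return total / (R * (R - 1) / 2 + C * (C - 1) / 2)


def bruteforce_spacer_scan(spacer: str, target: str, max_mm: int):
    """Exhaustive protospacer oracle: every window, both strands, string compare."""
    comp = str.maketrans("ACGTN", "TGCAN")
    hits = []
    k = len(spacer)
    for strand, probe in (("+", spacer), ("-", spacer.translate(comp)[::-1])):
        for start in range(len(target) - k + 1):
            window = target[start : start + k]
            mm = sum(
                1 for a, b in zip(probe, window)
                if a != b or a == "N" or b == "N"
            )
            if mm <= max_mm:
                hits.append((start + 1, strand, mm))
    return sorted(hits)
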