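"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re
from itertools import combinations

import pytest

from hydromine.motif_scan import ScanConfig
from hydromine.seqio import load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def default_config():
    return ScanConfig()


def subset_oracle(seq: str, config: ScanConfig) -> list[tuple[int, ...]]:
    """Brute-force motif finder: check every 8-subset of cysteine positions.

    Independent of the scanner's consecutive-window shortcut; only usable for
    sequences with modest cysteine counts.
    """
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    hits = []
    for sub in combinations(cys, 8):
        p = sub
        if p[2] != p[1] + 1 or p[6] != p[5] + 1:
            continue
        if any(c not in sub for c in cys if p[0] < c < p[7]):
            continue
        spacers = (
            p[1] - p[0] - 1,
            p[3] - p[2] - 1,
            p[4] - p[3] - 1,
            p[5] - p[4] - 1,
            p[7] - p[6] - 1,
        )
        if all(lo <= s <= hi for s, (lo, hi) in zip(spacers, config.spacer_bounds)):
            hits.append(sub)
    return sorted(hits)


def regex_oracle(seq: str, config: ScanConfig) -> list[tuple[int, ...]]:
    """Motif finder built directly on a regular expression with a lookahead.

    From a fixed first cysteine the rest of the motif is forced (every gap
    must be cysteine-free), so one overlapped match per start position
    enumerates all topologies.
    """
    b = config.spacer_bounds
    pat = re.compile(
        "(?=(C[^C]{%d,%d}CC[^C]{%d,%d}C[^C]{%d,%d}C[^C]{%d,%d}CC[^C]{%d,%d}C))"
        % tuple(x for pair in b for x in pair)
    )
    hits = []
    for m in pat.finditer(seq):
        g = m.group(1)
        hits.append(tuple(m.start() + i for i, aa in enumerate(g) if aa == "C"))
    return sorted(hits)
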