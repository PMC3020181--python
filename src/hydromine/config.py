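"""YAML configuration for the scanner and the spacing-class rule."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .motif_scan import ScanConfig
from .spacing_grammar import SpacingClassRule


def _pairs(raw) -> tuple[tuple[int, int], ...]:
    return tuple((int(lo), int(hi)) for lo, hi in raw)


def load_config(path: Union[str, Path]) -> tuple[ScanConfig, SpacingClassRule]:
    """Read a YAML file with optional ``scan`` and ``spacing_rule`` sections.

    Missing keys fall back to the package defaults, e.g.::

        scan:
          spacer_bounds: [[1, 25], [5, 50], [1, 30], [1, 12], [1, 50]]
          max_total_cys: 10
        spacing_rule:
          class1_s4: [5]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    scan_kw = dict(raw.get("scan") or {})
    if "spacer_bounds" in scan_kw:
        scan_kw["spacer_bounds"] = _pairs(scan_kw["spacer_bounds"])
    scan = ScanConfig(**scan_kw)

    rule_kw = dict(raw.get("spacing_rule") or {})
    if "class1_s4" in rule_kw:
        rule_kw["class1_s4"] = frozenset(int(s) for s in rule_kw["class1_s4"])
    if "class2_template" in rule_kw:
        rule_kw["class2_template"] = _pairs(rule_kw["class2_template"])
    rule = SpacingClassRule(**rule_kw)
    return scan, rule
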