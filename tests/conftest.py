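"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the package's own matching machinery:
motif scans are checked against a regex built by a separate, minimal
translator applied at every start offset, and clade assignments against a
dendropy-based bipartition enumeration.
"""

from __future__ import annotations

import re

import pytest

from peroxfam import synthetic


# --- independent regex-based motif oracle ----------------------------------


def spec_to_regex(spec: str) -> re.Pattern:
    """Translate the motif grammar to a regex, lazily-quantified so the
    shortest match at each offset is produced (mirroring the scanner's
    minimal-gap contract)."""
    out = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "[":
            j = spec.index("]", i)
            out.append("[" + spec[i + 1 : j] + "]")
            i = j + 1
        elif c == "X":
            if i + 1 < len(spec) and spec[i + 1] == "{":
                j = spec.index("}", i)
                out.append("." + spec[i + 1 : j + 1] + "?")
                i = j + 1
            else:
                out.append(".")
                i += 1
        else:
            out.append(re.escape(c))
            i += 1
    return re.compile("".join(out))


def oracle_scan(seq: str, spec: str) -> list[tuple[int, int]]:
    """Exhaustive per-offset match list as 1-based inclusive (start, end)."""
    rx = spec_to_regex(spec)
    hits = []
    for i in range(len(seq)):
        m = rx.match(seq, i)
        if m is not None:
            hits.append((i + 1, m.end()))
    return hits


@pytest.fixture(scope="session")
def oracle():
    return oracle_scan


# --- shared synthetic datasets ---------------------------------------------


@pytest.fixture(scope="session")
def clean_dataset() -> synthetic.SyntheticDataset:
    """Default-composition 19-species dataset with zero corruption."""
    return synthetic.generate_dataset(synthetic.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def clean_annotation(clean_dataset):
    from peroxfam import pipeline

    return pipeline.annotate(clean_dataset.records, clean_dataset.hits)
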