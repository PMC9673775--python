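import io

import pytest

from toothratio import AnteriorWidths, CrossTable3

#: Bilateral-mean widths (mm) of the normal-ratio reference group.
REFERENCE_MEANS = {
    ("upper", "central"): 8.650,
    ("upper", "lateral"): 7.216,
    ("upper", "canine"): 8.007,
    ("lower", "central"): 5.654,
    ("lower", "lateral"): 6.172,
    ("lower", "canine"): 6.961,
}

_CODE_KEY = {
    11: ("upper", "central"), 21: ("upper", "central"),
    12: ("upper", "lateral"), 22: ("upper", "lateral"),
    13: ("upper", "canine"), 23: ("upper", "canine"),
    31: ("lower", "central"), 41: ("lower", "central"),
    32: ("lower", "lateral"), 42: ("lower", "lateral"),
    33: ("lower", "canine"), 43: ("lower", "canine"),
}

#: Published 3x3 validation cross-table (rows SATR, cols gold standard).
VALIDATION_TABLE3 = ((29, 5, 0), (13, 59, 2), (0, 12, 22))


@pytest.fixture
def reference_record() -> AnteriorWidths:
    """A subject whose every width equals its tooth-type reference mean."""
    return AnteriorWidths(
        subject_id="ref",
        widths={code: REFERENCE_MEANS[key] for code, key in _CODE_KEY.items()},
    )


@pytest.fixture
def validation_table3() -> CrossTable3:
    return CrossTable3(VALIDATION_TABLE3)


@pytest.fixture
def wide_csv():
    """Build an in-memory wide-layout CSV stream from (subject -> widths) rows."""

    def build(rows, group=None, codes=(13, 12, 11, 21, 22, 23, 33, 32, 31, 41, 42, 43)):
        header = "subject_id," + ",".join(str(c) for c in codes)
        if group:
            header += ",group"
        lines = [header]
        for sid, widths in rows.items():
            cells = [sid] + [
                "" if widths.get(c) is None else repr(widths[c]) for c in codes
            ]
            if group:
                cells.append(group[sid])
            lines.append(",".join(cells))
        return io.StringIO("\n".join(lines) + "\n")

    return build
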