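#!/usr/bin/env python
"""Regenerate the golden fixture files under fixtures/.

Each use case is written as compact MIF 3.0 XML next to a JSON manifest of
the loss categories its 2.5 downgrade must report.  The combined
all-features document is not materialized here (build it with
``psimif fixture --case all``).  Output is deterministic, so re-running
this script must leave the tree unchanged.
"""

import json
from pathlib import Path

from psimif import fixtures, xml_io

OUT = Path(__file__).resolve().parent.parent / "fixtures"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for case in fixtures.USE_CASES:
        g = fixtures.golden(case)
        xml_io.write_mif(g.document, dest=OUT / f"use_case_{case}.xml")
        (OUT / f"use_case_{case}.manifest.json").write_text(
            json.dumps(g.expected_loss, indent=2, sort_keys=True) + "\n")
    print(f"wrote {len(fixtures.USE_CASES)} fixtures to {OUT}")


if __name__ == "__main__":
    main()
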