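"""TIL decile handling: dual pathologist reads to responder calls.

Stromal tumor-infiltrating lymphocytes are scored into deciles (bin k means
10k to 10k+9 percent stromal area) by two pathologists; the reads are
averaged per timepoint and a patient is an immune responder when the
combined decile rises by MORE than one between pre- and post-treatment.
"""

import pandas as pd

from immunomri.tme import build_til_records

reads = pd.DataFrame(
    [
        # patient, timepoint, reader, decile
        ("A", "pre", 1, 0), ("A", "pre", 2, 1), ("A", "post", 1, 2), ("A", "post", 2, 2),
        ("B", "pre", 1, 1), ("B", "pre", 2, 1), ("B", "post", 1, 2), ("B", "post", 2, 2),
        ("C", "pre", 1, 8), ("C", "pre", 2, 8), ("C", "post", 1, 8), ("C", "post", 2, 8),
        ("D", "pre", 1, 2), ("D", "pre", 2, 2),  # no post-treatment tissue
    ],
    columns=["patient", "timepoint", "reader", "decile"],
)

for rec in build_til_records(reads):
    if rec.evaluable:
        verdict = "responder" if rec.responder else "non-responder"
        print(f"patient {rec.patient}: pre {rec.pre_combined:.1f} -> "
              f"post {rec.post_combined:.1f}  (delta {rec.delta_til:+.1f})  {verdict}")
    else:
        print(f"patient {rec.patient}: non-evaluable (missing timepoint)")
# A rises 0.5 -> 2.0 (+1.5, responder); B rises exactly one decile
# (non-responder by the strict > 1 rule); C is TIL-rich but stable.
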