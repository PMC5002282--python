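"""Per-residue conservation (C_score) from a PSSM or an alignment.

Writes a tiny PSI-BLAST-style PSSM by hand, parses it, and prints the
Jensen-Shannon divergence of each position against the BLOSUM62 background:
1 bit = perfectly conserved on a letter the background rarely shows,
0 = indistinguishable from background.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from consite import jensen_shannon, load_background, parse_pssm
from consite.conservation import AA_INDEX, AA_ORDER

background = load_background()  # BLOSUM62 marginal frequencies

head = "  ".join(AA_ORDER)
rows = []
profiles = {
    "W": [100 if a == "W" else 0 for a in AA_ORDER],   # fully conserved Trp
    "A": [100 if a == "A" else 0 for a in AA_ORDER],   # fully conserved Ala
    "G": [5] * 20,                                     # uninformative
}
for i, (letter, pct) in enumerate(profiles.items(), start=1):
    rows.append(f"{i:>5d} {letter} " + " ".join("0" for _ in range(20))
                + "  " + " ".join(str(v) for v in pct) + "  0.5 1.0")
text = ("\nLast position-specific scoring matrix computed\n"
        "            " + head + "   " + head + "\n" + "\n".join(rows) + "\n")

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "tiny.pssm"
    path.write_text(text)
    profile = parse_pssm(path, background)

print("pos  aa  C_score (bits)")
for i, letter in enumerate(profile.query):
    c = jensen_shannon(profile.frequencies[i], background.frequencies)
    print(f"{i + 1:>3d}   {letter}   {c:.3f}")

# A conserved tryptophan scores higher than a conserved alanine because Trp
# is rare in the background; the flat column scores near zero.
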