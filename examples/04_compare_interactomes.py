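"""Venn comparison of interactomes and functional-category summaries.

Builds two hit lists sharing exactly three proteins, prints the exact
Venn regions, then summarizes a 45-hit list by functional category.
"""

from trapscore import categorize, venn_counts
from trapscore.psm_io import ProteinAnnotation

shared = {"Dek", "Non2", "BSF"}
bait_alone = shared | {"Kap-a2", "Moleskin", "Modulo", "P32", "Nap1"}
bait_plus_partner = shared | {"Pkcdelta", "TfIIFalpha", "AP-3beta", "Ssrp"}

venn = venn_counts({"trap": bait_alone, "trap+partner": bait_plus_partner})
print(f"only trap:         {venn.count('trap')}  {venn.members('trap')}")
print(
    f"only trap+partner: {venn.count('trap+partner')}  "
    f"{venn.members('trap+partner')}"
)
print(
    f"overlap:           {venn.count('trap', 'trap+partner')}  "
    f"{venn.members('trap', 'trap+partner')}"
)
print()

ids = [f"hit{i}" for i in range(45)]
annotations = {
    pid: ProteinAnnotation(
        pid,
        category=(
            "ribosome structure/biogenesis/translation"
            if i < 14
            else "DNA replication/repair/packaging/cell division"
            if i < 20
            else "other"
        ),
    )
    for i, pid in enumerate(ids)
}
summary = categorize(ids, annotations)
for cat, n, frac in summary.as_rows():
    print(f"{cat:48s} {n:3d}  {round(100 * frac)}%")
print()
print(
    "Venn regions are exact exclusive partitions of the union; category\n"
    "percentages are whole-percent fractions of the hit list."
)
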