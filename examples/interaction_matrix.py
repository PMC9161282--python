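"""Build a gene x xenobiotic interaction map from curated-style records.

Records are filtered to human and to a MeSH-keyed chemical whitelist, then
deduplicated into (gene, chemical) pairs weighted by distinct supporting
publications; degrees and the heatmap matrix follow.
"""

from xenoprio import (
    ChemicalEntry, InteractionRecord, build_pairs, degree_ordered_axes,
    degrees, filter_records, matrix, pct_chemicals_with_pairs,
)

whitelist = [
    ChemicalEntry("bisphenol A", "C006780", "Non-Persistent Organic Pollutants"),
    ChemicalEntry("valproic acid", "D014635", "Clinical Drugs"),
    ChemicalEntry("methylmercury", "D008767", "Toxic Heavy Metals"),
    ChemicalEntry("benzo(a)pyrene", "D001564", "Air Pollutants"),
]

records = [
    InteractionRecord("CYP1A2", "bisphenol A", "C006780", "Homo sapiens",
                      frozenset({"101", "102"}), "decreases metabolism"),
    InteractionRecord("CYP1A2", "bisphenol A", "C006780", "Homo sapiens",
                      frozenset({"102", "103"}), "affects expression"),
    InteractionRecord("CYP1A2", "benzo(a)pyrene", "D001564", "Homo sapiens",
                      frozenset({"104"})),
    InteractionRecord("GSTM1", "valproic acid", "D014635", "Homo sapiens",
                      frozenset({"105", "106"})),
    # dropped: wrong organism
    InteractionRecord("GSTM1", "methylmercury", "D008767", "Mus musculus",
                      frozenset({"107"})),
    # dropped: chemical not on the whitelist (join is by MeSH ID)
    InteractionRecord("ABCB1", "caffeine", "D002110", "Homo sapiens",
                      frozenset({"108"})),
]

kept = filter_records(records, whitelist)
pairs = build_pairs(kept, whitelist)
print(f"{len(records)} records -> {len(kept)} after the human/whitelist "
      f"filter -> {len(pairs)} unique pairs\n")
for p in pairs:
    print(f"  {p.gene_symbol:<8} x {p.chemical_name:<16} "
          f"({p.group}): {p.n_refs} reference(s)")

d = degrees(pairs)
print("\nper-gene chemical degree:", d.gene_degree)
print("chemicals hit:", pct_chemicals_with_pairs(pairs, whitelist), "% of whitelist")

gene_axis, chem_axis = degree_ordered_axes(pairs, sorted(d.gene_degree), whitelist)
print("\nreference-count matrix (rows genes, columns MeSH IDs):")
print(matrix(pairs, gene_axis, chem_axis))
print("\nCell values are distinct supporting publications; 0 means no "
      "curated human interaction.")
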