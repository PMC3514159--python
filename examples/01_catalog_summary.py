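"""Merge the packaged two-orientation screen tables and count partners.

The two hit lists come from the same bait screened in both two-hybrid
orientations (bait-DB vs AD-ORF library, and the reverse).  The union
catalog is keyed by Entrez Gene ID; the bait's own homodimer entry is
included or excluded per count, matching the screen's published
conventions.
"""
from y2hnet import summarize_counts, tally_localization
from y2hnet.datasets import hoxa1_catalog

catalog = hoxa1_catalog()
with_bait = summarize_counts(catalog, include_bait_self=True)
no_bait = summarize_counts(catalog, include_bait_self=False)
tally = tally_localization(catalog, include_bait_self=False)

print(f"DB-orientation hits:           {with_bait['n_db_config']}")
print(f"AD-orientation hits:           {with_bait['n_ad_config']}")
print(f"found in both orientations:    {with_bait['n_overlap']}")
print(f"distinct partners (no bait):   {no_bait['n_partners']}")
print(f"co-purification confirmed:     {with_bait['n_confirmed']}")
print(f"BiFC-positive:                 {with_bait['n_bifc_positive']}")
print()
print("BiFC compartment tally (bait excluded):")
print(tally)
# n_any counts partners whose interaction pattern includes the compartment;
# n_exclusive those seen in that compartment alone.
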