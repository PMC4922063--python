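"""Resolve an isoform-specific expression loss that gene-level RPKM hides.

Simulates per-exon counts for a two-promoter gene in wild-type and
mutant tissue (3 vs 3, negative-binomial noise), with an 11.5-fold loss
planted on the M-isoform's specific first exon only.  Gene-level
quantification would average this away; the per-exon fold-change
profile exposes it.
"""

from recmap import call_isoform_specific_loss, exon_fold_change
from recmap.simulate import sim_exon_counts

table_wt, table_mut, truth = sim_exon_counts(
    planted_fc={"M-exon": 11.5}, dispersion=0.1, group_sizes=(3, 3), seed=1)

fcs = exon_fold_change(table_wt, table_mut)
print("exon      isoform  WT RPKM  mutant RPKM  fold change")
for fc in fcs:
    iso = table_wt.exons.loc[fc.exon_id, "isoform"]
    print(f"{fc.exon_id:<9} {iso:<8} {fc.mean_a:8.1f} {fc.mean_b:12.1f} "
          f"{fc.fold_change:10.2f}")

flagged = call_isoform_specific_loss(dict(table_wt.exons["isoform"]), fcs,
                                     threshold=2.0)
print(f"\nisoform-specific loss called for: {flagged} "
      f"(planted: M-exon at {truth.planted_exon_fc['M-exon']}-fold)")
print("Shared exons stay near 1x, so the loss is confined to one promoter's")
print("first exon - a regulatory, not gene-wide, effect.")
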