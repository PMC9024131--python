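"""Generate a synthetic developmental qPCR dataset and run priming QC.

Builds the default 44-sample study (24 whole embryos E11.5-E18.5, 11
heads, 9 forelimbs; 15 candidate genes, triplicate wells, 3 plates, 4
cDNA batches, one of which has failed random priming), then screens the
batches.  The flagged batch should be the one the generator corrupted:
its rRNA sentinel (18S) runs ~3 cycles late while the rest of the panel
does not move.
"""

from refstab import priming_qc, prepare, simulate

table, truth = simulate(seed=1)
print(f"dataset: {len(table.meta)} samples x {len(table.genes)} genes, "
      f"{len(table.wells)} wells")

collapsed, _ = prepare(table)  # plate-calibrates, then averages wells
report = priming_qc(collapsed, sentinels=["18S"])
print(report.per_batch.round(2))
print(f"\nflagged: {report.flagged_batches}  (truth: {list(truth.batch_offsets)})")
print("sentinel_deviation is the batch's median 18S Cq shift in cycles;")
print("panel_deviation is the same shift for the other 14 genes.")
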