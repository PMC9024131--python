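"""Grouped NormFinder on whole embryos, grouped by gestational age.

Grouped mode decomposes each gene's stability into intragroup variance
and a shrunken intergroup deviation d, and searches all gene pairs for
the combination whose deviations cancel best -- two genes may drift in
opposite directions between ages and jointly beat any single gene.
"""

from refstab import groups_from_meta, normfinder_grouped, prepare, simulate

table, _ = simulate(seed=1)
_, rq = prepare(table)
embryos = rq.subset("embryo")

res = normfinder_grouped(embryos, groups_from_meta(embryos.meta, "age_days"))
print("stability (lower = more stable):")
print(res.stability.sort_values().round(3))
print("\nshrunken intergroup deviations d~ (cycles, per age group):")
print(res.d_shrunk.round(2))
print(f"\nbest pair: {' + '.join(res.best_pair)} "
      f"(combined stability {res.best_pair_stability:.3f})")
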