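"""Simulate a MAGIC RIL panel and cluster its SNPs into LD blocks.

Generates 256 near-homozygous lines from a four-founder intercross with
six generations of single-seed descent, then partitions the 1500 SNPs
into LD blocks with the two-threshold network-clustering rule
(min pairwise r² ≥ 0.5, median r² ≥ 0.7, windows of ≤ 100 SNPs).
"""

from ldbayes import cluster_ld_blocks, simulate_magic_genotypes

g = simulate_magic_genotypes(n_lines=256, n_chrom=10, snps_per_chrom=150,
                             seed=1)
print(f"panel: {g.n_lines} lines x {g.n_snps} SNPs on "
      f"{len(set(g.chrom))} chromosomes")
print(f"residual heterozygosity: {(g.calls == 0).mean():.4f} "
      "(RILs are near-homozygous after selfing)")

blocks = cluster_ld_blocks(g, r1=0.5, r2=0.7, w1=10, w2=100)
sizes = blocks.sizes()
print(f"\n{blocks.n_blocks} LD blocks; "
      f"{(sizes == 1).sum()} singletons, "
      f"{(sizes >= 10).sum()} blocks with >= 10 SNPs, "
      f"largest {sizes.max()}")
print("mean SNPs per block:", round(float(sizes.mean()), 2))
# Each multi-SNP block is a run of markers inherited together from the
# founders; the block, not the SNP, is the unit of QTL inference below.
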