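"""Pseudohaploid calling from a per-site base-count table.

Builds the five-position read-stack example in the paired pos/counts text
dialect, runs the 2-of-3 consensus caller over it and prints the resulting
sequence: positions where two of three subsampled reads agree get that base,
1/1 disagreements and singleton coverage get N.
"""

import io

from consensify import ConsensifyParams, ScaffoldIndex, consensify_genome, read_counts

pos_text = """\
chr\tpos\ttotDepth
scaf1\t1\t3
scaf1\t2\t2
scaf1\t3\t2
scaf1\t4\t4
scaf1\t5\t5
"""
counts_text = """\
totA\ttotC\ttotG\ttotT
0\t0\t1\t2
0\t0\t2\t0
1\t0\t0\t1
4\t0\t0\t0
0\t4\t1\t0
"""

sites = read_counts(io.StringIO(pos_text), io.StringIO(counts_text))
index = ScaffoldIndex((("scaf1", 5),))
sequences, stats = consensify_genome(sites, index, ConsensifyParams(), rng=1)

print("read stacks (A,C,G,T):", counts_text.splitlines()[1:])
print("consensus sequence:   ", sequences["scaf1"])
print(f"{stats.sites_called} of {stats.sites_seen} covered sites called;")
print("position 3 is a 1/1 disagreement -> N; every other call is depth-safe.")
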