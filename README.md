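# permalign

Short-read alignment with **randomly permuted sorted M-mer indexes**.

Mapping a sequencer read `Y` to a reference genome `W` is a nearest-neighbor
search: among the `N - M + 1` length-`M` substrings `X_i` of `W`, find the one
at minimum Hamming distance from `Y`. A sorted array of the `X_i` finds exact
matches by binary search, but a single early mismatch throws the search to a
distant part of the array. permalign exploits the fact that *reordering the
characters of two strings the same way does not change their Hamming
distance*: it keeps several arrays of the same library, each sorted under a
different uniformly random permutation `π⁽ʲ⁾` of the `M` positions. A
permutation that happens to move all `p` mismatches past the first `L`
characters (the read's *resolution length*) puts the permuted read right next
to its permuted nearest neighbor, so a binary search plus a scan of the
`2K + 1` surrounding entries recovers it. One lookup is lucky with probability
at least

```
PrGoodPerm(p, L, M) = (M-L)! / (M-L-p)! · (M-p)! / M!
```

and `J` independent indexes succeed with probability at least
`1 − (1 − PrGoodPerm)^J`, which approaches 1 rapidly — the planner in
`permalign.theory` turns this into concrete `J`/`K` choices. Candidates
proposed by the lookups are filtered by *hit count* (how many lookups proposed
them), ranked by Hamming distance, and reported (optionally as SAM). The
package also provides paired-end alignment with an indel-tolerant mate-rescue
step, a sliding-window mode that reuses one index for long reads, and a
wgsim-style simulator that generates genomes, haplotypes, and reads with
ground truth for self-contained evaluation.

## Worked example

The permutation convention is *gather*: output position `j` takes the input
character at `order[j]` (1-based in printed codes, 0-based in the API).

```python
import permalign as pa

perm = pa.Permutation.from_one_based((11, 2, 7, 13, 9, 15, 4, 5, 1, 12, 10, 14, 3, 8, 6))
print(perm.apply("CTTGCCAAAGCCATG"))     # CTAAAGGCCCGTTAC
print(pa.permute_position(perm, 2) + 1)  # 13 — a mismatch at position 3 moves to 13

genome = pa.generate_genome(20_000, seed=1)
lib = pa.build_library(genome, 15)       # 19 986 library 15-mers
indexes = pa.build_indexes(lib, 8, seed=2)

read = list(lib.mmer(10_000)); read[2] = "A"; read = "".join(read)  # plant 1 mismatch
res = pa.align_read(read, indexes, lib, pa.SearchParams(j=8, k=20))
print(res.best)  # ReportedAlignment(position=10000, strand='+', distance=1, hit_count=4)

L = pa.resolution_length(indexes[0], 10_000, k=20)
print(L, pa.pr_success(1, L, 15, 8))     # 5 0.999848...
print(pa.required_iterations(1, L, 15, target=0.999))  # 7
```

The read with one planted mismatch is recovered at its true locus (distance 1,
proposed by 4 of the 8 lookups), in line with the theoretical success bound of
0.9998 for `p = 1` mismatch, resolution length `L = 5`, `M = 15`, `J = 8`.

The same machinery is available from the shell:

```sh
permalign simulate --out-prefix sim --genome-length 1000000 --n-reads 10000
permalign index --reference sim.fa --out sim.idx.npz -m 100 -j 8 --seed 7
permalign align --reference sim.fa --index-file sim.idx.npz --reads sim.fq --out sim.sam
permalign evaluate --sam sim.sam --truth sim.truth.tsv
permalign plan -p 2 -l 10 -m 100 --target 0.99
```

`align-pe` does the paired-end equivalent with insert-size bounds and mate
rescue.

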