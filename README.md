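# hybnum

Hybrid numbers of ploidy profiles.

A *ploidy profile* is a descending vector of positive integers, one per
taxon (e.g. the number of chromosome-set copies per species).  A rooted
binary phylogenetic network — parallel arcs ("beads") allowed — *realizes*
the profile when its root-to-leaf directed path counts equal the vector.
The *hybrid number* of the profile is the minimum number of hybrid vertices
over all such networks, i.e. the minimum number of polyploidization events
needed to explain the data.

`hybnum` computes this number exactly for a large class of profiles and
returns certified lower/upper bounds with an explicit certificate network
otherwise.

## What is inside

| module | contents |
|---|---|
| `hybnum.netcore` | `PhyloNetwork` (rooted DAG multigraph with beads), `PloidyProfile`, validation, path counting (dynamic programming *and* an independent path-enumeration cross-check), and the local surgeries (subdivision, cherry expansion, hybridization, pendant leaves) |
| `hybnum.numrep` | binary/bitwise representation, descending prime factorization, `ceil_log2` |
| `hybnum.constructions` | `beaded_tree`, the binary-representation realization `build_B`, the prime-decomposition realization `build_D`, the ladder-gadget `naive_realization`, and the closed-form `theorem1_vertex_count` |
| `hybnum.simplify` | the simplification sequence (merge / subtract steps with full provenance), its length `s`, subtract count `c`, and the `alpha > m2` flag |
| `hybnum.traceback` | `build_N` (reverse the sequence from a terminal realization) and `build_N_auto` |
| `hybnum.hybridnumber` | memoized iterative-deepening exact search over open-path-count multisets, a brute-force network enumeration oracle, `attain_simple`, and the top-level `hybrid_number` |
| `hybnum.cli_io` | profile/network file formats, worked-example fixtures, seeded random profiles, and the `hybnum` CLI |

The top-level result is exact when either

* every component is a power of two (a bead chain with pendant leaves meets
  the `2^h` path-count lower bound), or
* no simplification step had `alpha > m2` and the terminal simple profile is
  small enough for the exact search — then
  `h = h(terminal) + #subtract-steps`, certified by the traceback network.

Otherwise the result carries certified bounds: the lower bound from
`ceil_log2` and head-only search, the upper bound from the best of the
traceback network, the per-component star of B-networks, and the naive
ladder realization, each a verifying network.

## CLI

```sh
# hybrid number of a profile (exact value or bounds, JSON report)
hybnum hybrid-number --profile viola.tsv --report report.json --certificate net.tsv

# the simplification sequence as JSON
hybnum simplify --profile profile.tsv --out sigma.json

# explicit realizations: B, D, naive, or a bead chain
hybnum construct --method B --profile profile.tsv --out net.tsv --enewick net.nwk --dot net.dot

# the traceback network
hybnum build-n --profile profile.tsv --out net.tsv

# does a network realize a profile?  exit code 2 if not
hybnum check --network net.tsv --profile profile.tsv

# worked-example profiles plus their expected values
hybnum fixtures --out-dir fixtures/
```

### File formats

* **Profile TSV** — `label<TAB>ploidy`, one taxon per line, `#` comments.
* **Arc-list TSV** — `tail<TAB>head` per arc; parallel arcs are repeated
  lines; out-degree-0 vertices are leaves and their name is the taxon label;
  a line with a single token declares an isolated vertex (only used by the
  degenerate one-vertex network).  Written in sorted order so write→read→write
  is byte-stable.
* **Extended Newick** — hybrid vertices carry `#Hk` tags numbered by first
  appearance in a root-down DFS; the first occurrence of a tag carries the
  children, later occurrences are bare references.  A bead is the tag twice
  under one parent: `((x1)#H1,#H1);`.
* **DOT** — hybrid vertices drawn filled.

## Notes and conventions

* Profiles with head 1 (all ones) are realized by plain trees; the n = 1
  case uses the degenerate single-vertex network, the one deliberate
  exception to the root-out-degree-2 convention.
* The exact search explores multisets of open-arc path counts with
  iterative deepening on the hybrid count, memoizing failed states; its
  minima coincide with brute-force enumeration of all single-leaf binary
  networks for up to three hybrids (tested), and with minimal addition-chain
  lengths for the searched heads (observed, not relied upon).
* `hybnum.cli_io.random_profile(seed, n, max_entry)` is the seeded fixture
  generator used throughout the randomized tests.
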