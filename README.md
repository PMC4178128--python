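# degenlib

A toolkit for designing and budgeting degenerate-codon saturation-mutagenesis
libraries. It computes the amino-acid distribution of any IUPAC degenerate
codon (NNN, NNK, NNM, ...), library-completeness probabilities and minimum
screening sizes, simulates random clone picking (a coupon-collector problem
with unequal probabilities), optimizes the hybrid "screen randomly, then
site-directed-mutagenize the missing variants" strategy under a cost model,
and designs QuikChange-style degenerate and completion primers.

## Library overview

| Module | Contents |
|---|---|
| `degenlib.genetic_code` | standard genetic code, IUPAC expansion, `amino_acid_distribution`, `reverse_complement` (exact `Fraction` probabilities) |
| `degenlib.library_stats` | `completeness_probability` (inclusion–exclusion or per-variant product), `min_library_size`, `expected_distinct`/`expected_missing`, `expected_collection_time`, `probability_monotypic` |
| `degenlib.simulate` | `simulate_screening` (per-discovery-rank clone counts, bit-reproducible), `simulate_fixed_screen` |
| `degenlib.strategy_cost` | `CostModel`, `evaluate_strategy`, `optimal_switch_point`, `realized_cost` |
| `degenlib.primer_design` | `design_degenerate_primer_pair`, `design_completion_primers`, `TemplateCDS` |
| `degenlib.cli_io` | `degenlib` CLI, report writers, `generate_fixture_template` |

```python
from degenlib import (amino_acid_distribution, LibraryDesign, DegenerateCodon,
                      min_library_size)

dist = amino_acid_distribution("NNK")
design = LibraryDesign(DegenerateCodon("NNK"), dist.reachable_amino_acids)
min_library_size(design, dist)  # clones for 95% completeness
```

## CLI

```bash
degenlib dist --scheme NNM --include-zero            # variant probabilities
degenlib size --scheme NNN --targets all20           # min library size (L*)
degenlib simulate --scheme NNM --iterations 1000000 --seed 1 -o sim.tsv
degenlib cost --scheme NNM --targets all20 --screen-cost 20 --sdm-cost 100
degenlib primers --scheme NNM --template cds.fa --codon-pos 373 \
    --complete CEIMNQVY --fasta-out primers.fa
degenlib report --scheme NNM --format json           # combined design report
```

Outputs are TSV (with a `# config:` header line) or JSON (`--format json`);
every artifact embeds its full run configuration, including the seed, so it
can be regenerated from its own metadata. Logs go to stderr only.

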