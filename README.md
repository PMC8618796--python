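# wickerkey

Phenotypic character matrices, dichotomous identification keys, and
diversity bookkeeping for yeast taxonomy — built around the genus
*Wickerhamomyces* (Saccharomycetales, Wickerhamomycetaceae) as the
flagship data set.

## Who this is for

Yeast taxonomists describe species with batteries of growth and
assimilation tests (carbon/nitrogen sources, growth temperatures,
vitamin-free medium) plus a few morphological observations, summarize
them in a species × character table, and publish a dichotomous key for
identification. Those three artifacts — table, key, distribution
records — are usually frozen prose. `wickerkey` makes them executable:

* **Character-state algebra.** Test outcomes use a small token grammar:
  `+` (strong positive), `‒` (negative), `w` (weak), `l` (latent), `s`
  (slow), `v` (strain-variable), `n` (no data), and alternations such as
  `w/+` or `+,‒`. A state is a set of atomic outcomes; a state *supports*
  a binary lead outcome ("is assimilated" / "is not") under a named
  polarity rule (default: weak/latent/slow count as positive).
* **Keys as data.** A key is a set of numbered couplets, each with two
  leads asserting opposite outcomes of one character and pointing at
  another couplet or a species. Parsing, structural validation (tree
  shape, `leaves = couplets + 1`, printed parent-annotation checks),
  serialization, and uncertainty-aware traversal: a variable state forks
  the walk, a missing observation stalls it.
* **Key ⟷ matrix validation.** For every species: can its table row reach
  its own leaf (existential over resolutions of variable states)? Which
  other species can reach the same leaf?
* **Greedy key construction.** Builds a key from a matrix by maximizing
  the expected log-reduction in taxon count per couplet, penalizing
  characters whose uncertain states force taxa onto both sides.
* **Occurrence summaries.** Species-per-continent/country counts and
  decade histograms from literature-compiled distribution tables, with an
  explicit, editable place → continent mapping.
* **Synthetic data.** Seeded generators for matrices with a realistic
  state-token mix, resolved specimens, and occurrence tables, so every
  stage is testable end to end.

The packaged fixtures are a cleaned transcription of the published
summary data for *Wickerhamomyces*: the 38 species × 22 character
matrix, the 37-couplet key, the 36-species distribution table, and
specimen profiles for the two recently described Thai soil species,
*W. lannaensis* and *W. nanensis*.

## Worked example

```python
from wickerkey import fixtures, identify, validate_structure

key = fixtures.load_key()
profile = fixtures.load_profile("nanensis")   # the W. nanensis ex-type profile
result = identify(key, profile)
print(result.species, result.status)
print(result.path)
```

prints

```
W. nanensis identified
[(1, 'b'), (7, 'b'), (19, 'b'), (21, 'b'), (23, 'a'), (24, 'b'), (25, 'b'), (26, 'a')]
```

i.e. the specimen walks the printed key: melibiose not assimilated (1b),
raffinose not (7b), 2-ketogluconate not (19b), D-arabinose not (21b),
galactose assimilated (23a), L-arabinose not (24b), sucrose not (25b),
D-mannitol assimilated (26a) → *W. nanensis*.

Structural validation of the same key finds its one transcription-level
fault:

```python
print(validate_structure(key).annotation_discrepancies)
# [{'couplet': 26, 'printed': 24, 'actual': 25}]
```

couplet 26 is printed with back-reference "(24)" although the lead that
reaches it belongs to couplet 25.

The same operations are available from a shell:

```sh
wickerkey identify --profile nanensis
wickerkey validate-key
wickerkey build-key --allow-multi-species-leaves --out built.json
wickerkey summarize
wickerkey synth matrix --n-species 8 --n-characters 8 --seed 7
wickerkey fixtures --list
```

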