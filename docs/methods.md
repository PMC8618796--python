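# Methods

## The data model

A phenotypic character matrix is a species × character grid whose cells
are drawn from the standard yeast-taxonomy scoring vocabulary: strong
positive (`+`), negative (any dash glyph), weak (`w`), latent positive
(`l`), slow positive (`s`), strain-variable (`v`), no data (`n`), and
alternations joining two or more atoms with `/` or `,` (published tables
mix both separators, e.g. `w/+` and `+,‒`). A cell is modeled as a
non-empty set of atomic outcomes; `n` never mixes with other atoms.
Unicode dash variants (hyphen-minus, en dash, em dash, figure dash,
minus sign) normalize to negative at parse time because published tables
typically use a figure dash. Canonical serialization orders atoms
`+ < w < l < s < v < -` and joins with `/`; the TSV writer emits
canonical tokens, so write→parse→write is bit-exact.

## Two comparison semantics

Two distinct questions arise, and they need different granularity:

**Binary support** (`state_supports`) bridges table states and key leads,
which only ever assert "assimilated" / "not assimilated". Under the
default polarity rule, `+`/`w`/`l`/`s` support the positive lead, a dash
supports the negative lead, and `v`/`n` support both; an alternation
supports an outcome if any atom does. Weak, latent and slow count as
positive because species descriptions report "weak" and "delayed
positive" growth as assimilation. A strict mode lets `w` support both
outcomes, for auditing borderline cells; with it, every state still
supports at least one outcome, so key traversal can never hit a dead
end.

**Atom-level distinguishability** (`distinguishing_characters`) asks
whether two species can *ever* be told apart on a character. Here `+`
vs `w` does distinguish — the table records them as different scored
outcomes — while `v` and `n` expand to every concrete outcome and hence
never distinguish, and alternations sharing an atom never distinguish.
Binary support would be too coarse for this purpose (it would collapse
`+` and `w`), and the published diagnoses themselves lean on exactly
such contrasts (e.g. nitrate assimilation `+` vs `w` between the two
newly described Thai species).

## Key traversal under uncertainty

Identification walks couplet to couplet taking the unique lead the
specimen supports. Two failure modes are deliberately distinct because
their remedies differ: a character *missing* from the profile stalls the
walk (the user must run the test), while a state supporting *both* leads
forks it (the strain is genuinely variable) and the result reports the
frontier of reachable species.

`reachable_leaves` computes that frontier as a depth-first expansion
carrying per-character outcome commitments: once a path reads a
character as positive, deeper couplets on the same path must read it the
same way. This makes the expansion exactly equal to enumerating every
concrete resolution of the row and walking each one deterministically —
the brute-force oracle the test suite checks against on small matrices.
A naive frontier expansion without commitments could visit leaves no
real strain could reach whenever a key reuses a character along one
path.

Consistency checking is existential: a species is consistent with a key
when *some* resolution of its row reaches its own leaf. Variable states
describe real strain-level variation, and published keys separate
variable-state species by other characters downstream, so a universal
reading would flag working keys. On the packaged fixtures, all 38
species are consistent with the published key — a computed finding, not
an assumption.

## Greedy key construction

`build_key` recursively partitions the taxon set. For each character it
places taxa supporting only the positive outcome on side *a*, only the
negative on side *b*, and taxa supporting both on *both* sides (the key
must work whichever way the strain behaves — this mirrors how printed
keys implicitly handle `v` taxa). A split is admissible only if both
sides are non-empty and neither keeps the full set, which guarantees
termination and implies no character is reused along a path, bounding
depth by the character count. The score is the expected log-reduction
in taxon count (natural log), minus a penalty of 0.5 per duplicated
taxon — enough to prefer a clean split over an uncertain one of equal
gain without forbidding uncertain characters outright. Ties break by
vocabulary (column) order, making construction deterministic. An
alternative worst-case-balance scoring (minimize the larger side) is
provided. Unsplittable sets either raise an error naming the taxa or
become multi-species leaves, per configuration. The builder is greedy
only: minimal-expected-depth key construction is NP-hard and greedy
information gain is the standard approach for single-access key
generation; reproducing the exact topology of any particular published
key is a non-goal.

## Occurrence summaries

Localities are stored verbatim from the source table (including
non-country places) and resolved through an explicit two-column mapping;
the default is a UN-style geoscheme with pins for the fixture's border
cases (Russia → Europe, Dominican Republic → North America, King George
Island → Antarctica, Ivory Coast → Africa). A species counts once per
continent where it has at least one locality and may count on several
continents. Under this mapping the fixture reproduces the published
South America (8), Africa (7), Oceania (1) and Antarctica (1) figures,
and the Thailand bookkeeping (8 species before, 10 after the two new
descriptions, 38 worldwide). The published Asia/Europe/North-America
figures are *not* reproducible from the distribution table under any
single consistent mapping (USA records alone exceed the printed North
America count); the tool reports what the table yields and the mapping
is deliberately not tuned toward the printed numbers. Decade histograms
bin caller-supplied discovery years as `floor(year/10)·10`; years
outside 1800–present are rejected.

## Synthetic data

Generators are pure functions of an integer seed (one NumPy `Generator`
per call). `gen_matrix` draws cells from a configurable state-mix; the
default mix is all-definite (half positive, half negative), and
`empirical_state_mix` derives a realistic mix from the packaged matrix
at run time rather than hard-coding frequencies. With the
distinguishability guarantee, rows of indistinguishable pairs are
resampled from the same mix up to a retry cap (default 64), so a mix
that cannot distinguish (e.g. all no-data) fails honestly rather than
silently bending the mix. `gen_specimen` resolves variable states and
alternations uniformly at random to one admitted concrete outcome and
drops no-data cells, emulating a strain on the bench. What the
generators do *not* emulate: phylogenetically correlated characters,
assay-specific error rates, or inter-laboratory scoring drift — so
passing round-trip tests shows the machinery is sound, not that real
strains are always identifiable.

## Problem sizes and numerical choices

The oracle-equivalence suite enumerates all outcome resolutions on
matrices up to 6 × 6 (≤ 2⁶ walks per row, >100 rows checked) and on the
flagship key with three extra no-data cells injected into mostly
definite rows. The round-trip suite runs 100 seeded replicates of
6-species × 5-character definite matrices (600 identifications); these
sizes exercise every code path while keeping the whole suite around two
seconds. Scores are compared with strict `>` so earlier columns win
ties; information gain of a degenerate split is never computed because
degenerate splits are filtered before scoring.

## Known limitations

* Ordered/quantitative characters (cell sizes, growth rates) are out of
  scope; only the categorical scoring vocabulary is modeled.
* No DELTA/NEXUS import and no multi-access (polyclave) identification.
* One fixture ambiguity is documented rather than resolved: the matrix
  encodes *W. lannaensis* vitamin-free growth as `w`, and its species
  description calls it "weak positive" — consistent under the default
  polarity rule, but strict mode reads the cell as either outcome.
* Name matching normalizes the genus abbreviation and whitespace only;
  there is no fuzzy matching or synonym resolution.
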