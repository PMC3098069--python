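# granopart

Typed part-whole partonomies, granular partitions, integrated granularity
perspectives and structural granularity values for cumulative-constitutively
organized material entities (most biomedical anatomy: not every molecule sits
in an organelle, not every cell in an organ).

The library models partonomies over the three material-entity kinds —
`object`, `fiat_object_part`, `object_aggregate` — and provides:

- **core_model** — strict-partial-order validation of instance-level
  parthood (irreflexivity, antisymmetry, reduction discipline of the
  `direct_proper_part_of` edges), transitive closure/reduction, and
  mereological exhaustive-sum checks with graph-theoretic atoms.
- **partition_tree** — granular partitions as rooted trees with cuts
  (instance granularity levels); bona fide / fiat / mixed classification.
- **sedimentation** — type granularity from instance granularity: a type
  settles at the lowest level any of its instances occupies; detection of
  level-crossing types (the hallmark of cumulative organization).
- **perspectives** — the compositional-object backbone perspective plus
  two-level compositional, spatial, and resolution (countable vs mass
  representation) perspectives, instance-only fiat-part chains, overcross
  detection, framework validation and the numbered instance rules.
- **values** — structural granularity values: fixed naturals on the
  backbone, exact-rational open intervals for fiat/aggregate levels,
  nested sub-intervals for fiat chains (stable under later deepening),
  monotonicity checking, measure-threshold size perspectives.
- **scheme_lint** — external published schemes as ordered level lists,
  audited against the seven classical granularity principles, the two
  general principles, the single-level lookup contract, and consistency
  rules (mixed compositional/spatial levels, `object aggregate` misuse).
- **synthetic_data** — deterministic cumulative-constitutive generators
  and bundled fixtures (a worked cumulative organ with three cuts, a
  compositional chain, a nested fiat-part chain, a twelve-level
  human-anatomy scheme, the seven salient + five transitional anatomy
  levels).
- **io_cli** — canonical JSON partonomy documents (byte-identical round
  trips), TSV edge lists, a restricted OBO 1.2 importer with a kind map,
  DOT export, value tables, and the `granopart` CLI.

## CLI

```bash
granopart simulate --seed 7 --levels 4 --branching 3 --free-fraction 0.3 \
    --ecm --fiat-parts 3 -o organ.json
granopart validate -i organ.json          # exit 0 clean, 1 findings, 2 bad input
granopart tree -i organ.json --levels     # cut listing (or DOT by default)
granopart sediment -i organ.json          # type levels + crossing types
granopart perspectives -i organ.json      # framework as JSON (or --dot)
granopart values -i organ.json --tsv      # structural granularity values
granopart lint keet -i organ.json         # framework + instance rules
granopart lint kumar -i doc.json --scheme kumar_human
granopart lint scheme -i doc.json --scheme fma_salient
granopart import-obo -i anatomy.obo -f obo --kind-map kinds.json
```

A kind map is a JSON object mapping term ids (or `PREFIX*` patterns) to a
kind string, or to `{"kind": ..., "name_giving_object_type": ...}` for
fiat parts and aggregates.

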