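# File formats

All tables are tab-separated with a comment header carrying the package
version and a hash of the generating configuration:

    # seqerp 0.1.0
    # config_hash 5c1f0a2b3d4e

## Session tables (`seqerp simulate`, pipeline `session0/`)

- `trials.tsv` — index, onset_ms, digit, colour, role
  (random / cue / sequential), block.
- `sequences.tsv` — sequence, cue_type (short / long), compliance
  (terminated / regular / extended), start_index, realized_length
  (sequential digits including the cue), block, cued_colour (learned / new).
- `events.tsv` — BIDS-events-like: onset_ms, duration_ms, trial_index,
  klass (CP_term_check / CP_ext_check / PE_termination / PE_extension /
  STD), sequence, uncertainty (low / high).
- `task_config.yaml` — the full task configuration.

## Behaviour

- `responses.tsv` (input) — participant, press_time, release_time (ms from
  stream start).
- `latencies.tsv` — participant, sequence, block, uncertainty, compliance,
  cue_type, cued_colour, onset_latency, offset_latency (ms), I (surprise,
  nats), excluded (offset latency outside [−500, 2000] ms or missed).
- `summary.tsv` — participant, scope, n_sequences, hits, misses,
  false_alarms, pr.
- `groups.tsv` — participant, gain_score (ms), group (gain / no_gain).
- `surprise.tsv` — sequence, outcome, p, I_nats, scope.
- `statistics.tsv` — tidy statistics: stage, effect, statistic, df, p,
  p_adjusted.

## Epochs (HDF5)

- `/epochs` — n_epochs × n_channels × n_times, µV.
- `/times` — ms relative to event onset.
- `/channels/names`, `/channels/coords` — names and 2-D positions.
- `/labels` — condition string per epoch (PE / CP / STD).
- attributes: `participant`, `seqerp_version`, `config_hash`.

## Cluster tests

`cluster_result.json` — mode (sampled / enumerated), df, n_comparisons,
threshold_t, and per cluster: mass, sign, corrected p, member count.
Channel adjacency overrides are JSON objects mapping channel name to a
list of neighbour names.

## Microstates

- `templates.tsv` — channel × template topography matrix.
- `segments.tsv` / `microstate_segments.tsv` — condition, template, onset
  (ms), duration (ms), mean_gfp (µV), one row per template visit.
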