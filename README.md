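# painsim

A headless re-implementation of the computational core of a serious game
for postoperative pain-management education, plus the questionnaire
scoring and pre/post statistical battery used to evaluate such a game.

The player's avatar has come home after surgery. Over three simulated
24-hour days (09:00 to 09:00) the player balances household tasks against
pain management: taking any of four analgesics (each with onset, peak and
wear-off kinetics, dose limits, and side-effect triggers), resting,
or using distractions. Pain is a 0–10 NRS value that relaxes toward a
baseline minus current relief. High pain reduces mobility, making
movement-requiring chores slower and eventually impossible. Once per day
a random "unmanageable pain" episode may pin pain at ≥ 8 and stop it
responding to medication until the player calls the help line, after
which pain drops to 5. Each day has a goal (day 1: minimize medication;
day 2: keep pain under 3; day 3: under 5) scored 1–3 stars, and ends with
an after-action review: the pain curve overlaid with classified nodes
(doses, relieving activities, impairing activities, side-effect
outlines).

All numeric constants (medication kinetics, baselines, thresholds,
probabilities) live in JSON config under `src/painsim/data/`, not in
code, and can be overridden with `--config-dir`.

## Modules

| module | contents |
|---|---|
| `painsim.simulation_core` | pain/medication dynamics engine (`Engine`, `dose_relief`, `mobility_factor`) |
| `painsim.world` | activity catalog, task lists, `perform_activity` |
| `painsim.session` | day/session drivers, goals and star ratings, unmanageable events, consult, monologue |
| `painsim.telemetry` | append-only event log, after-action-review timeline, exports |
| `painsim.instruments` | AttrakDiff2 / POP-MGS / BQ-II / PAK-PPM scoring; median+IQR, Wilcoxon signed-rank (exact by enumeration for small n), Cronbach alpha, KR-20 |
| `painsim.synth_agents` | scripted player policies and synthetic questionnaire respondents |
| `painsim.cli` | `painsim` command-line entry point |

## CLI

```sh
# simulate a full 3-day session with a built-in policy
painsim run --policy scheduled_dosing --seed 7 --out out/

# after-action review from a day log (JSON/CSV, optional PNG)
painsim review --log out/day1_log.json --out review/ --format json --format csv

# generate synthetic pre/post knowledge respondents
painsim synth respondents --n 20 --uplift 0.17 --seed 1 --out responses.csv

# score an instrument / compare pre vs post
painsim score --instrument pak_ppm --responses responses.csv
painsim compare --instrument pak_ppm --responses responses.csv

# tabulate outcome metrics for every built-in policy across seeds
painsim synth run-policies --seeds 20 --out results.csv

# interactive text-mode play
painsim play --seed 0
```

Built-in policies: `no_med`, `prn_wait_for_severe`, `scheduled_dosing`,
`rest_and_distract`, `random`. Exit codes: 0 success, 2 configuration or
usage error, 3 runtime error. All randomness derives from `--seed`; the
same seed reproduces byte-identical outputs.

## Response-sheet format

Questionnaire responses are long-format CSV with columns
`respondent,instrument,timepoint,item,answer`. Instrument definitions
(items, scales, subscales, reverse keying, correct answers) are JSON
files under `src/painsim/data/instruments/`; custom definitions can be
passed to `--instrument` by path.
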