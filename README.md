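# sociobadge

**Sociometric-badge stream simulation and interprofessional contact-network
analysis for hospital wards.**

Wearable sociometric badges record who met whom, when, where and for how
long: dyadic infrared (IR) detections while two wearers face each other,
body-motion frequency from a built-in accelerometer, and location pings from
infrared beacons installed throughout a ward. `sociobadge` implements the
full analysis path from those raw event streams to interprofessional
communication networks in an intensive-care unit (ICU):

1. **detect** — segment IR detections into face-to-face episodes and keep
   the *active* ones: episodes longer than 1 minute in which a participant's
   body-motion frequency exceeds 2 Hz (gesture-aided conversation);
2. **map** — localize each interaction to one of 42 functional areas
   (14 beds, the central nurses' station, lounges, labs, …, instrumented
   with 249 beacons) by majority vote of beacon pings, and build daily
   occupancy / hot-spot summaries;
3. **network** — accumulate active minutes into a person × person contact
   matrix, aggregate it into a 9-profession pair heatmap (log₁₀ scale),
   threshold it at 1/3/4/30/150/180 cumulative minutes into layered
   sociograms, and compute degree, eigenvector and betweenness centrality
   plus a core/periphery fit on each layer;
4. **synthgen** — because no raw badge data are publicly deposited, a
   first-class synthetic generator emulates the study conditions: 76 staff
   across 9 professions (39 nurses, 15 attending physicians, …), a 3-shift
   day with handovers every 8 hours, 160 mean on-duty hours over 4 weeks,
   and nurse-centred profession-pair mixing.

The package is aimed at researchers studying interprofessional communication
with proximity sensors, and at anyone needing a reproducible test bed for
contact-network methods on badge-like event streams.

## The statistics at the core

* **Active-interaction rule.** An episode between badges *i, j* with
  duration *d* and per-participant mean motion *m_i, m_j* is active iff
  *d* > 1 min and max(*m_i*, *m_j*) > 2 Hz (both inequalities strict; the
  motion rule is configurable to `both` or `mean`).
* **Contact matrix.** *W_ij* = Σ durations of active interactions between
  *i* and *j* over the analysis window (symmetric, zero diagonal).
* **Sociogram at threshold t.** Edge {i, j} iff *W_ij* ≥ *t* (and
  *W_ij* > 0). Raising *t* peels the network down to its most communicative
  core, so edge sets are nested across thresholds.
* **Centrality.** Degree *k_v* (raw and *k_v*/(n−1)); eigenvector
  centrality as the leading eigenvector of the binary adjacency (shifted
  power iteration on A + I, unit Euclidean norm, non-negative); betweenness
  *Σ_{s≠v≠t} σ_st(v)/σ_st* by Brandes' algorithm (raw and normalized by
  (n−1)(n−2)/2).
* **Core/periphery fit.** The binary partition maximizing the Pearson
  correlation between the observed adjacency and the ideal block pattern
  (core–core dyads = 1, periphery–periphery = 0, core–periphery dyads
  excluded) — exhaustive up to 15 nodes, seeded steepest-ascent label swaps
  beyond.

## Worked example

```python
import pandas as pd
import sociobadge as sb

roster   = sb.make_roster()                      # 76 staff, 9 professions
zones    = sb.make_zone_map()                    # 42 areas, 249 beacons
schedule = sb.make_schedule(roster, n_days=7)    # 3-shift week, 40 h/person
streams  = sb.simulate_streams(roster, schedule, zones, seed=1)

episodes = sb.attach_motion(sb.segment_episodes(streams.ir), streams.accel)
active   = sb.classify_active(episodes)          # 2 Hz / >1 min gates

cm  = sb.contact_matrix(active, roster)
pm  = sb.profession_heatmap(cm, roster)
g   = sb.threshold_graph(cm, 30.0)
fit = sb.core_periphery_fit(g, seed=1)
rep = sb.centrality_report(g, roster)
```

With seed 1 this prints (via the obvious `print` statements):

```
13099 episodes, 10410 active (36805 active pair-minutes)
nurse-nurse cell: 18152 min (log10 display 4.26)
threshold 30 min: 455 edges, core size 34 (97% nurses), fit r=0.47
daily profile peaks: 3 at bins [0, 8, 16]
```

Reading: of ~13k face-to-face episodes in the simulated week, ~10k pass the
active gates. Nurse–nurse contact dominates the profession heatmap; at the
30-minute threshold the sociogram has a core of 34 badges that is almost
entirely nurses (doctors sit in the periphery), and nurses hold better
median ranks than attending physicians on all three centrality measures.
The 60-minute-binned intensity profile, averaged over the week, peaks
exactly three times per day — at the 8-hour-spaced shift handovers
(bins 0, 8 and 16).

## Command line

```bash
sociobadge run --config config.yaml --seed 1 --out run/       # full pipeline
sociobadge simulate --seed 1 --out raw/                       # stages also
sociobadge detect --in raw/ --out interactions.csv            # run one by
sociobadge map --interactions interactions.csv \
              --beacons raw/beacon.csv --zones raw/zones.csv --out occ/
sociobadge network --interactions interactions.csv \
              --roster raw/roster.csv --thresholds 1,3,4,30,150,180 --out net/
```

Each full run writes `run_manifest.json` recording the config snapshot,
input digests and per-stage record counts.

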