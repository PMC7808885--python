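# Methods

This note documents the models, parameter choices and numerical conventions
behind `sociobadge`, and what the synthetic test bed does and does not show
about real badge data.

## 1. What the badges record, and what we infer

A sociometric badge emits three event streams: dyadic IR detections (a
record whenever another badge is in the facing cone), per-badge body-motion
frequency samples from the accelerometer, and pings from wall-mounted
location beacons. The analysis treats these as given; radio/IR propagation,
detection latency and within-zone geometry are out of scope. Corridors carry
no beacons, so interactions are only ever localized to functional areas.

### Episode segmentation

IR records are direction-symmetrized (A-sees-B and B-sees-A are the same
evidence) and grouped per unordered pair; a maximal run whose inter-record
gaps do not exceed **60 s** becomes one episode, ending one IR tick after
its last detection. The gap tolerance bridges brief occlusions (a turned
head, a passing colleague) without merging distinct meetings; it is
configurable. The IR sampling tick defaults to **10 s**, fine enough that a
1-minute episode spans ≥ 6 ticks; badge hardware intervals vary by vendor
and deployment, so the tick is a parameter rather than a constant.

### The active gates

An episode is an *active* interaction — gesture-aided conversation rather
than mere co-presence — when its duration strictly exceeds **1 min** and
the motion gate strictly holds at **2 Hz**. How the 2 Hz statistic is
computed over an episode is underdetermined by the rule itself; we use the
per-participant **mean of the per-minute motion samples** falling in
`[start, end)`, and apply the gate to **either** participant (max of the two
means) as the permissive reading of "gesture-aided"; `both` and `mean`
variants are a config switch. A participant with no motion samples in the
window gets mean 0 and a flag — absence of evidence never passes a strict
gate.

### Zone assignment and conservation

An interaction's zone is the majority vote of both participants' beacon
pings during `[start, end)`; pooling the two badges is symmetric and robust
when a pair straddles an area boundary. Ties go to the zone pinged earliest;
interactions with no usable ping land in an explicit `unassigned` bucket so
that, for any day, zone minutes + unassigned minutes always equal the day's
active-interaction minutes (asserted at 1e-9 relative tolerance). Episodes
spanning midnight belong to the day they start; only intensity binning
splits durations, apportioning each interaction to bins by overlap so the
bin sum is conserved.

## 2. Network analysis

Connectivity is the cumulative active pair-minutes matrix *W*. Sociograms
threshold *W* at 1, 3, 4, 30, 150 and 180 minutes; the edge rule is
inclusive (*W_ij* ≥ *t*) so that threshold 1 means "at least one minute",
but zero entries never link. Centralities are computed on the **binary**
thresholded graph — the layering across thresholds, not edge weights,
carries the duration information.

* **Degree**: raw and /(n−1).
* **Eigenvector**: power iteration restricted to the largest connected
  component (the measure is ill-defined across components; other nodes score
  0 and the restriction is flagged in the report). Iteration uses **A + I**:
  the shift leaves eigenvectors unchanged but makes the Perron eigenvalue
  strictly dominant in modulus, so bipartite components converge instead of
  oscillating. Start is uniform positive; convergence is max-norm change
  < 1e-10, capped at 1000 iterations (flag on failure). Scores are
  non-negative with unit Euclidean norm over the scored component.
* **Betweenness**: Brandes' single-source accumulation, exact for
  unweighted graphs; raw pair counts and normalization by (n−1)(n−2)/2.
* **Core/periphery**: maximize Pearson r between the adjacency and the
  ideal pattern over core–core and periphery–periphery dyads only
  (core–periphery dyads are unconstrained in the ideal and excluded).
  Exhaustive enumeration for n ≤ 15; otherwise steepest-ascent single-label
  flips from 20 seeded random starts. Labelings whose evaluated dyads make
  either vector constant have undefined r and are skipped; if the optimum is
  all-core/all-periphery (or nothing is defined) the result carries a
  degeneracy flag. Deterministic given the seed.

The profession heatmap sums *W* over unordered badge pairs into a 9 × 9
matrix, displayed as log₁₀(x + 1) to keep zero cells finite.
Intra-profession cells of single-member professions are masked N/A. The
"minutes × people" unit admits two readings; `pair_minutes` (each pair
counted once) is the default and `person_minutes` (×2, once per
participant) is a switch — neither is asserted as canonical. "Top 3"
doctors/nurses are flagged by cumulative minutes at the layer's threshold,
ties broken by badge id; profession summaries use median average-ranks
(rank 1 = most central).

## 3. The synthetic ward

The generator's defaults *are* the study conditions: 76 staff
(15 attending physicians, 39 nurses, 4 senior residents, 1 resident,
4 nursing assistants, 8 medical technicians, 2 receptionists, 1 pharmacist,
2 secretaries); 42 functional areas with 249 beacons (the per-area beacon
split is synthetic, summing to the installed total); three 8-hour shifts
starting 00:00/08:00/16:00 local (fixed UTC+09:00 offset); 160 mean on-duty
hours per person over 28 days, scaled pro rata for shorter runs. The
deterministic scheduler gives each badge round(target/8) shifts spread
evenly over the days, rotating through the three slots so staffing is
balanced; shifts never overlap within a badge.

Encounters between a co-on-duty pair follow a thinned Poisson process at
the profession-pair rate (encounters per co-on-duty pair-hour) modulated by
a within-shift profile *f*(phase): a ×4 burst during the 30-minute handover
window after each shift start, then a log-linear V from 1 down to 0.20 at
mid-shift and back. The V makes the *expected* 24-bin daily intensity
profile strictly unimodal at each handover and monotone between handovers;
its depth and the overall encounter volume were sized together by a noise
budget so that adjacent-bin contrasts exceed ≈3 sampling standard deviations
at desk scale (76 staff, 7 days) — a flat baseline would instead make one
in three bins a spurious strict local maximum. Default rates put nurse–nurse
contact highest (1.55/pair-h), nurses mixing broadly, nursing assistants
talking to nurses but rarely doctors, and a 0.17 floor elsewhere; a nurse
spends roughly 10–25 min per hour in face-to-face contact depending on
shift phase, consistent with observational workload studies.

Episode durations are log-normal (median 2 min, log-sd 0.8) — the heavy
right tail matches conversational-contact literature — truncated at shift
end so records never leave a badge's duty interval. Motion samples are
drawn once per minute: conversing minutes at mean 2.5 Hz, idle at 1.0 Hz,
sd 0.5, truncated at 0, placing the 2 Hz gate between the modes (≈80 % of
encounters pass both gates). Encounter zones are drawn from the pair-averaged
profession propensities over area categories (then uniformly within the
category); idle pings follow the individual's propensity. Nurse mass
concentrates on beds (0.56) and the central station (0.30), reproducing the
bedside/station hot-spot structure. Reproducibility: one master seed,
labelled SHA-256-derived child seeds per component (encounters, durations,
zones, motion, beacons).

**What the generator does not emulate:** patient agents and
patient-directed care events; day/night staffing asymmetry; inter-day
heterogeneity in acuity (and hence the severity–intensity correlation seen
in real wards); badge dropout, clock drift or asymmetric IR detection;
within-zone positions. Tests passing on this synthetic ward therefore
validate the *pipeline's* correctness and the recoverability of an injected
nurse-centred structure — not claims about any particular real ICU.

## 4. Problem sizes and numerical conventions

Desk-scale runs use 76 staff over 7 simulated days (≈10k encounters, ≈350k
IR records), which the full pipeline processes in a few seconds; unit tests
use a 16-badge 2-day ward. Timestamps are written as ISO 8601 with the
explicit +09:00 offset at 1-second resolution (event times are floored to
whole seconds at generation, so CSV round-trips are lossless). Daily
profiles treat the 24-bin day as periodic when counting strict local maxima
— a handover sits at midnight, whose neighbours wrap. Ties are resolved
deterministically everywhere (lexicographic badge/zone ids; earliest ping
for zone votes). Degenerate inputs are contracts, not crashes: empty
rosters run cleanly end to end, edgeless graphs reject eigenvector
centrality and the core/periphery fit with explanatory errors, and
malformed CSV rows are dropped, counted and warned about.

## 5. Known limitations

* The greedy core/periphery search is a local optimizer; with 20 restarts
  it matched the exhaustive optimum on all tested 10-node graphs, but global
  optimality is not guaranteed at 76 nodes.
* Concurrent overlapping encounters of one badge are resolved with a
  bounded back-scan when labelling conversing minutes; badges in 4+
  simultaneous conversations could be mislabelled idle (vanishingly rare at
  the default rates).
* The statistical significance of profession differences is out of scope;
  the package reports magnitudes and ranks only.
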