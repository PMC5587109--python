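# Methods

This note documents the models, parameters and design choices behind
`p300composer`: what the simulation emulates, what it deliberately does not,
and which decisions were genuinely open.

## Stimulation model

A selection block flashes the rows and columns of an `R × C` matrix. Each
*sequence* is an independent uniform permutation of the `R + C` groups;
successive flash onsets are spaced by the stimulus-onset asynchrony
SOA = flash duration + inter-stimulus interval. Defaults follow the study
protocol: 50 ms flashes, 125 ms ISI (SOA 175 ms), up to 15 sequences per
block. One randomization constraint is imposed beyond uniformity: the first
group of a sequence may not equal the last group of the previous one (the
permutation is redrawn), the standard oddball precaution against immediate
repetitions; boundary handling is otherwise unspecified by the protocol. The
inter-sequence gap defaults to 0 s — pauses exist between selection blocks
(4 s calibration, 6 s spelling, 10 s composing), not between sequences.
Element indices are 0-based row-major throughout.

## Synthetic EEG

`signal_sim` emulates what the decoder actually consumes, not scalp
biophysics:

- **Montage/rate**: Fz, Cz, Pz, PO7, PO8, Oz at 250 Hz, amplitudes in µV.
- **Background noise**: AR(1) with coefficient 0.95 per channel, innovation
  variance scaled so the stationary SD equals `noise_sd` (default 4 µV).
  AR(1) gives the 1/f-like low-frequency power that makes single-trial ERP
  detection realistically hard; white noise is available but unrealistically
  easy. Channels are independent — real EEG is spatially correlated, so
  spatial filtering gains are *under*-represented here.
- **P300**: a half-cosine (Hann) bump, width 300 ms, peak `p300_amplitude`
  (default 5 µV) centered 300 ms after every flash of a group containing the
  attended element. Topography weights: Pz = Cz = 1.0, PO7/PO8/Oz = 0.6,
  Fz = 0.4 — the parietal maximum is the defining P300 property; the exact
  values are free parameters in `RecordingParams`.
- SNR is controlled through the single ratio `p300_amplitude / noise_sd`.
  The defaults (5/4) were chosen once as a realistic "good participant"
  operating point: calibration passes the 70% criterion comfortably and
  closed-loop runs show occasional errors, comparable to the high-accuracy
  human results the system reported.

What the generator does **not** model: eye/muscle artifacts, latency and
amplitude jitter of the P300, habituation and target-to-target interval
effects, spatial noise correlation, non-stationarity. Passing tests therefore
demonstrate correctness of the decoding and stopping machinery under
idealized ERP statistics, not expected performance on recorded EEG.

A 0.5 s lead-in of plain background precedes the first flash so every marker
has a pre-stimulus baseline; 1 s of tail covers the last epoch window.

## Preprocessing

4th-order Butterworth band-pass, 1–15 Hz (`scipy.signal.butter(4, (1, 15),
'bandpass')`; "order" is the design order passed to the filter designer).
The online decoding path filters causally, matching a real-time system whose
epochs must be available immediately; zero-phase filtering is available for
offline analysis. Epochs are 0–800 ms post-flash with a −100–0 ms baseline
subtraction, a window that contains the 300 ms component with margin — the
original preprocessing beyond the filter was not documented, so these are
configurable rather than fixed. At 175 ms SOA adjacent epochs overlap and
share samples, as in any rapid-serial P300 paradigm.

## Decoding

Features: per-channel block averaging of the epoch by a decimation factor of
12 (≈ 21 Hz feature rate, 17 values per channel, 102 per epoch), channels
concatenated. Classifier: linear discriminant with Ledoit–Wolf
shrinkage-regularized pooled covariance; the shrinkage intensity comes from
`sklearn.covariance.ledoit_wolf` and a tiny ridge floor (plus an
identity-covariance fallback for exactly zero within-class variance) keeps
the solve well-posed in the noiseless limit used by construction tests.
Training is deterministic.

Element scoring adds the row and column discriminant scores and accumulates
them across sequences within a block; ties at the argmax break toward the
lowest row-major index so logs are reproducible. The protocol text does not
state whether the original system accumulated evidence across sequences or
re-classified each sequence independently before the agreement check; this
implementation accumulates, and applies the three-in-a-row agreement rule to
the per-sequence argmax history. Accumulation makes the running argmax
"sticky" under pure noise, which is also what lets zero-signal blocks
terminate by agreement at chance-level accuracy rather than resetting
forever.

**Dynamic stopping**: select when the last three sequence decisions agree
(minimum three sequences); at 15 sequences without agreement, reset —
accumulators and history restart from zero, matching a stimulation that
"starts again". The original system had no documented bound on resets (a
human simply kept going); a simulation needs one, so `max_resets` (default 3,
i.e. up to four stimulation blocks) caps a selection, after which the
controller reports no selection (`stopped_by='max-reset'`); the session layer
counts that as an incorrect selection. In practice agreement terminates
virtually all blocks well before the cap.

**Calibration**: six letters ("H3P5FU") × 15 sequences, leave-one-letter-out:
train on five letters' epochs, decode the held-out letter from its first
n sequences for n = 1…15; accuracy(n) is the fraction of letters correct and
the run passes when any accuracy exceeds 70%.

## Session simulation

The simulated user attends the intended element, or with probability
`lapse_probability` a uniformly random other element (modeling attention
lapses; decoding noise already comes from the signal). Timing is bookkept
from the stimulation parameters: a selection lasts
`n_sequences × (R + C) × SOA` plus a configurable overhead term (default 0),
with the task's pause between consecutive selections. The study reported an
*effective* inter-selection pause of 11.5 s against a configured 10 s; the
unexplained 1.5 s is not guessed at — the `overhead` field exists for users
who want to reproduce wall-clock figures.

Copy-spelling never corrects errors (per protocol). Copy-composing follows a
deterministic greedy planner: it emits the cheapest next token toward the
target melody (length token only when the length changes, octave steps as
needed, one-shot modifiers per use, then the pitch), and after a
misclassification it first navigates to the earliest wrong note and deletes
it before resuming — so correction costs are reproducible. The error-free
planner stream defines `min_selection_count`, which for the bundled melody is
41 (entry "Compose" + 39 note-entry selections + final "play all"). The run
aborts at the first selection count ≥ 62 from which finishing within 70 is
impossible, operationalizing the protocol's 62–70 abort window. Spoken
experimenter corrections are modeled as an oracle that repairs the user's
intention stream, never the decoder.

**Alouette fixture**: the melody of the copy-composing task exists only as a
printed figure; `data/alouette.json` is a six-bar synthetic reconstruction in
F major, 4/4, calibrated so that its minimum selection count equals the
documented 41. It is a fixture consistent with the task's arithmetic, not
ground truth.

## Composer grammar

Defaults: treble clef, 4/4, quarter note, octave 4 (middle C), on an empty
sheet. The cursor sits *on* a note; insertion goes after the cursor and the
cursor moves to the new note — the original software's insertion point was
reported ambiguous by its users, so one unambiguous rule is fixed here.
One-shot modifiers (accidental, dot) toggle when re-selected and are consumed
by the next insertion; deleting that note does not re-arm them. Notes
inserted while slur is latched share a slur group; pitches inserted while
chord is latched attach to the note at the cursor as chord members (sharing
its onset and duration). MusicXML (partwise, hand-rolled writer/reader with
canonical group numbering, byte-stable round trip) and format-0 Standard MIDI
File are the export formats; notes crossing a barline are kept whole in their
starting measure (no ties), and audio codecs are out of scope.

## Questionnaires

NASA-TLX: ratings on the 20-step 0–100 grid (multiples of 5; a lenient flag
accepts any value, since the electronic version's granularity is not
documented), weights = win counts of the 15 pairwise comparisons (sum 15,
each ≤ 5), contribution = weight × rating / 15, global = sum — so one factor
tops out at 33.3 and the global score at 100. UEQ: the bundled standard
26-item map (attractiveness 6 items; perspicuity, efficiency, dependability,
stimulation, novelty 4 each) with per-item polarity; item value = response − 4
with reverse-keyed items negated; use quality = mean(efficiency, perspicuity,
dependability), design quality = mean(novelty, stimulation). Impression
labels are strict: > 0.8 positive, < −0.8 negative, boundary values neutral.
(Published applications of the instrument occasionally label a value slightly
above 0.8 as neutral, presumably from pre-rounding; the scorer follows the
stated rule.) Paired pre/post comparisons use the paired t-test with Cohen's
d = mean(diff)/sd(diff); a constant nonzero difference is flagged degenerate
rather than silently reported as ±∞.

## Test and acceptance problem sizes

The acceptance suite exercises the closed loop at: 100 noiseless trials
(expected: all correct, exactly three sequences each), 200 zero-signal trials
(accuracy within the binomial 95% CI of 1/36), and a three-point SNR grid
(amplitude 0.5/1.5/4.0 µV on 4 µV noise, 50 trials per point) whose spacing
dominates binomial noise, so the expected monotone accuracy ordering is
testable with strict inequalities. Dynamic stopping is checked exhaustively
against a brute-force reference over all decision strings of length ≤ 8, and
the grammar's one-shot/latch invariants over 10,000 random command streams.
These sizes keep the full suite in the tens of seconds while leaving each
check statistically decisive at its stated tolerance.
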