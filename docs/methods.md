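# Methods

This note records the models, parameters and design choices behind
`trapkit`, and what the synthetic test bed does and does not show about
real camera-trap data.

## Data model

A project is defined by a *template*: an ordered list of typed field
specifications.  Four standard fields — `File`, `RelativePath`,
`DateTime`, `UtcOffset` — are always present, come first, and are
maintained by the system; user fields follow in template order, which is
also the column order of every exported table.  Values are stored as
text and typed on demand; per-type storage rules are:

| type | storage rule | empty means |
|---|---|---|
| Note | free text | not yet entered |
| Choice | member of the field's ordered list | not yet entered |
| Counter | non-negative base-10 integer | not yet entered |
| Flag | `true` / `false` (lowercase) | — (defaults to `false`) |
| DateTime | `YYYY-MM-DDTHH:MM:SS`, 4-digit year | — |
| UtcOffset | signed decimal hours in [−14, 14] | — |

Counters accept 0: recording the *absence* of an entity is a routine
observation, even though counts are colloquially "positive".  Choice
fields also accept the empty string as a distinct not-yet-entered state;
a project wanting an explicit "none" should add it to the list.
Two-digit years are rejected at parse time rather than guessed.
Templates persist as JSON with a fixed key order, so equal schemas are
byte-identical on disk; the record database persists in a single-file
SQLite database whose one data table has exactly the schema's columns
(the template, counter markers and the audit log are stored beside it,
making the file self-describing).

## Image operations

**Luma.** All brightness comparisons use ITU-R BT.601 luma,
`round(0.299 R + 0.587 G + 0.114 B)`.

**Differencing.** A pixel of the pair mask is white iff the absolute
luma difference exceeds `luma_threshold` (default 40).  The combined
mode is the *conjunction* of the differences against the previous and
next frames: anything shared with either neighbour — the static
background, or an entity present across all three frames — is
suppressed, leaving only what is unique to the current frame.  Masks are
monotone in the threshold by construction.

**Darkness.** An image is `Dark` iff it is essentially greyscale
(≥ 90 % of sampled pixels have max−min channel spread ≤
`color_tolerance`, default 40) **and** the fraction of sampled pixels
with luma < `pixel_threshold` (default 60) is at least `dark_fraction`
(default 0.9).  The greyscale gate models infrared night illumination:
night frames carry no chroma, while a dark daytime frame (dusk, shade)
keeps its colour cast and stays `Ok`.  Whether colour should enter the
darkness test at all is a design choice of this package; the thresholds
are analyst-configurable.  Sampling stride defaults to 1 (exact); a
larger stride trades exactness for speed on large frames.

## Timestamp repair

All corrections touch only the `DateTime` column and append to an audit
log; replaying the log on a pristine table reproduces the corrected one.

*Drift* is interpolated by **elapsed time**, not image index: with
recorded first/last times `t_first`, `t_last` and the analyst-supplied
true last time, each record moves by the total error times
`(t_i − t_first)/(t_last − t_first)`, rounded half-up to whole seconds
(residual ≤ 0.5 s by construction).  The first image is assumed correct
and anchors the line; an optional `first_correct` overrides the anchor.
*DST* shifts either the pivot-to-end or start-through-pivot range by
±1 h.  *Day/month swap* is an involution and refuses the whole selection
if any selected date has day > 12.  Date-text classification calls
`a/b/yyyy` *ambiguous* when both the day-first and month-first readings
are valid calendar dates **and differ**; when `a = b` the readings
coincide, so the token is classified unambiguous.

## Entry operators

Backfill copies the last non-empty value into the *empty* intervening
records only, and into the current record unconditionally (whether a
non-empty current value should be overwritten is genuinely open; setting
it matches the operator's intent of "bring that value here").
Forward/copy-to-all overwrite their whole range.  Copy-previous honours
the template's `copyable` flag and never touches system fields.  Text
prediction returns the **most recently** committed matching entry —
recency, not frequency, because field sessions are strongly
autocorrelated (the value just entered is the best guess for the next
image).

## Selection and sorting

Queries are flat criterion lists under a single global AND/OR — exactly
the expressive power of the select dialog they model — compiled to a
parameterized SQL WHERE clause and executed on an SQLite copy of the
table.  Counter/UtcOffset comparisons are numeric with the convention
that an empty (never-entered) value matches no numeric criterion;
DateTime compares chronologically (the ISO text orders correctly); text
compares case-insensitively, with `contains` as substring match.  The
test suite holds the compiled path equal to an independently written
in-memory evaluator over hundreds of random tables.  Sorting is a stable
one- or two-key sort under the same typed comparisons; empty values sort
first (a convention — they represent work not yet done and should be
seen, not buried).

## Episodes

Records are time-sorted (ties broken by path) and split at every gap
strictly greater than the threshold; a gap exactly equal to the
threshold stays within the episode.  Grouping runs over the whole set by
default; `per_folder=True` restricts runs to one folder for sets that
interleave stations in time.  Labels are `i/n` within multi-image
episodes and `Single` for singletons.  Episode grouping ignores any
camera burst-counter metadata in favour of the time heuristic, since one
event routinely spans several back-to-back trigger sequences.

## The synthetic test bed

`trapkit.synthgen` generates what the rest of the package is measured
against: JPEG frames in timed bursts (default 5 bursts of 2–5 frames,
10 s within a burst, 600 s between bursts — so any episode threshold
strictly between the two must recover the bursts exactly), a flat
background of luma 49 with one 25-pixel blob of luma 200 per daytime
frame at a seeded random position, three trailing greyscale night frames
of luma ≈ 12 forming a final burst, and injected EXIF
(`DateTimeOriginal` plus vendor-style tags such as `Ambient Temperature`
written as text `key=value` lines in the maker note — the dialect the
metadata reader decodes; real binary maker notes are out of scope).
Identical spec and seed give byte-identical files.

Numerical margins are chosen so JPEG compression cannot flip a test:
quality is fixed at 95, blob/background contrast (≈ 150 luma) is more
than three times the differencing threshold (40), blob positions within
a burst are ≥ 8 px apart per axis, and day frames carry a green colour
cast (channel spread ≈ 50 > the 40 greyscale tolerance) at unchanged
luma so the darkness gate separates day from night deterministically.

What passing on this bed shows: the algorithms implement their stated
semantics exactly — recovered episodes, mask areas, dark flags,
timestamps and metadata equal the planted ground truth bit-for-bit.
What it does not show: robustness to the ways real imagery is messy —
wind-moved vegetation, illumination swings, camera shake (all of which
break frame differencing), dusk frames near the darkness boundary,
vendor-specific binary maker notes, or corrupt EXIF.  Those require real
data and analyst review; the package's role there is to make the review
cheap, not to replace it.

## Problem sizes and verification

The shipped test suite and the acceptance script run entirely on
generated data at small scale — 100 image sets of ~20 frames at
64×48 px for episode recovery, 500 random tables of up to 200 records
for the query/sort oracle comparisons, 96×72 px frames for the pixel
and metadata checks — sizes at which every oracle is exact and the whole
suite completes in seconds.  All randomness is seeded; the acceptance
script derives every stream from its `--seed` argument.
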