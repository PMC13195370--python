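# Methods

## Threat model and the blindness property

Three parties handle a donation.  The *client* holds the plaintext and its
own network address.  The *deidentification proxy* is semi-trusted: it is
relied on to mask addresses but treated as an adversary with respect to
content — it observes client addresses and ciphertext only, performs no
cryptographic operations, and retains nothing after a transaction.  The
*donation database* is the only holder of the private key; it observes
plaintext but, by construction, only ever the proxy's address as a peer.

The testable form of the blindness claim: over any run, the set of
components that observe a client address and the set that observe plaintext
intersect only at the client.  The harness checks it two ways: every stored
donation's recorded TCP peer is one of the proxy's outbound socket
addresses, and an audit scans all proxy log streams for any ≥16-character
substring of any observed envelope's base64 ciphertext fields.

Transport-layer protections (TLS, certificate pinning, IPsec), at-rest
volume encryption, and denial-of-service defenses are deployment concerns:
transport here is a pluggable loopback HTTP channel, and the store layout is
documented so an operator can mount an encrypted volume.  There is
deliberately no payload-layer MAC: CBC is malleable, and envelope integrity
rests on the transport in deployment.  Inside this package, tampering is
detected at the two points where it necessarily surfaces — OAEP
decapsulation failure for the key ciphertext, and PKCS#7 padding or CSV
schema failure for the payload ciphertext — and mapped to stage-specific
error codes.

## Cryptographic choices

* AES-128 in CBC mode with PKCS#7 padding; the IV travels as the first 16
  bytes of `c1`, keeping the envelope exactly the two-field object
  `(c1, c2)`.  The block core is table-based, derived at import from the
  GF(2^8) field arithmetic, and pinned to FIPS-197 / SP 800-38A vectors in
  the tests.
* RSA-OAEP with SHA-256 for both the label hash and MGF1 (the padding
  standard leaves the hash open; SHA-256 is current practice and both ends
  must agree).  Default modulus 2048 bits, configurable upward; generation
  rejects anything smaller.  Any decapsulation failure is reported as one
  opaque error, as OAEP requires.
* The symmetric key exists only inside the `encrypt` call on the client
  side; nothing derived from it is cached.  Fresh key and IV per donation
  mean compromise of one donation affects no other.
* Keys serialize to interoperable PEM (PKCS#8 / SubjectPublicKeyInfo);
  the encoding was cross-checked against OpenSSL during development.

## Payload format and screening

The CSV dialect is pinned — comma separator, UTF-8, LF, minimal quoting,
fixed column order, ISO-8601 dates, canonical shortest decimal rendering —
so that serialization is byte-deterministic.  Determinism matters twice:
ciphertext comparisons in tests, and stable row identity for deduplication.

Questionnaire answers come from closed per-key vocabularies; free text is
not reliably anonymizable, so none is admitted.  Identifier screening
checks every field label (questionnaire keys, lab analyte labels) against a
name/regex policy covering direct identifiers, location, hardware
fingerprints, ECG waveforms and genetic data.  Screening rejects rather
than repairs: the wire contract stays clean and the client must fix its
snapshot.  Schema validation on the server is strict and reports the first
offending line.

The column set is a faithful but invented stand-in — no public schema
exists for the kind of app export modeled here.  The schema has no
operational defense against quasi-identifier *combinations* (rare lab
panels plus dates); that is a known open problem, not addressed.

## Scheduling

Donations are quarterly, read as a fixed 90-day period (calendar-month
arithmetic is irregular and would make the cadence drift).  The first
donation falls one full period after consent, so the 24-hour pre-donation
reminder has a window to act in before anything is ever sent; afterwards
the cadence anchors to the last successful donation.  A 365-day horizon
therefore yields four donations, at days 90, 180, 270 and 360.

Failures queue a retry with backoff (1 h, 6 h, 24 h, then daily).  A retry
never replays the failed bytes: the client re-snapshots the complete
current dataset, preserving full-donation semantics; the quarterly
re-donation cadence makes this idempotent under deduplication.  Opting out
stops all future donations and nothing else — anonymized data cannot be
selected for deletion, because no link between person and dataset exists.

## Identifier-free deduplication

Row identity is the canonical content tuple (section, category, date,
rendered value, analyte/key, answer).  Including the value, not just
category and date, is what keeps coincidental cross-donor collisions rare:
full snapshots re-donate identical historical rows verbatim, while two
donors rarely share an exact measured value on the same date across many
rows.

Linkage is greedy and chronological: donations are scanned in receipt
order; each is compared to the current tail of every existing cluster and
joins the best-overlapping one iff the overlap of that *earlier* snapshot
contained in the new one reaches the threshold (ties toward the most recent
tail); otherwise it founds a new cluster.  This matches how re-donations
actually arise — each one extends a single prior snapshot — and is linear
in cluster count per donation.  The threshold 0.8 operationalizes
"significantly large subset": it tolerates client-side edits and deletions
up to well above the simulated 5–10% rate while separating unrelated
donors, and is exposed as `--threshold`.  Overlap against an empty earlier
snapshot is defined as 0: an empty snapshot carries no linkage evidence.

The procedure is heuristic by nature and the failure modes are inherent:
two donors with coincidentally identical tiny snapshots merge (constructed
worst case in the tests), and a donor who wipes their dataset splits.
Duplicates can be reduced, not eliminated, and donors can never be
re-contacted to resolve ambiguity.

## Plausibility and outlier rules

Per-category admissible intervals: resting heart rate (20, 250] bpm —
open below, closed above, so 250 itself is retained while anything above
is physiologically impossible; systolic pressure [60, 260] mmHg; diastolic
[30, 160] mmHg; sleep [0, 24] h; steps [0, 200000] per day; laboratory
results are analyte-specific and carry no generic bound.  Filtering drops
offending rows and reports each with the violated rule; it is idempotent
and never touches questionnaire entries.

Statistical outliers are excluded per (category, analyte) group pooled
across payloads: a value is excluded when it deviates from the pooled
median by more than k = 5 median absolute deviations.  Robust statistics
avoid the masking that the outliers themselves would cause in a
mean/standard-deviation rule.  Guards: groups under 10 values pass through
(no stable scale estimate), and zero MAD disables the rule for the group (a
constant offers no scale to judge deviation against).

## The synthetic cohort

The generator emulates the study conditions the architecture faces:

* Donors accrue rows by independent per-category Poisson processes
  (defaults, per day: steps 1.0, resting heart rate 1.0, sleep 1.0, each
  blood-pressure component 0.3, lab results 0.05 — roughly one wearable
  sample per vital per day plus occasional labs).
* Values are drawn inside the plausibility intervals so that any validator
  rejection isolates adversarial behavior: resting HR ≈ N(65, 8) bpm,
  systolic ≈ N(125, 15), diastolic ≈ N(78, 10) mmHg, sleep ≈ N(7.2, 1.1) h,
  steps log-normal with median 7000, and a five-analyte lab panel.
* Enrollment is spread evenly across the feasible window with small
  per-donor jitter, so a one-year horizon yields one to four quarterly
  donations per donor.
* Between donations an `edit_rate` fraction (default 5%) of the rows present
  in the previous snapshot is edited — half deleted, half re-measured — so
  consecutive snapshots are near-supersets with expected containment 1 − e.
* Adversarial clients (a configurable fraction) cycle through four
  archetypes: schema-breaking CSV, a planted forbidden field, implausible
  values inside a valid schema, and raw byte garbage.  The first, second and
  fourth fail server-side schema validation; the third passes syntax and is
  caught by the plausibility stage.
* Everything derives from one integer seed (NumPy `SeedSequence` spawning
  per donor); identical configs produce byte-identical streams.

What the generator does **not** model: realistic epidemiological structure
or correlations between vitals, device-specific noise and gaps, the
download-to-donor adoption funnel, or real network behavior beyond
loopback.  Passing tests therefore demonstrate the mechanics of the
architecture — encryption, blindness, statelessness, recovery of known
ground truth under the stated accrual/edit model — not field performance on
real cohorts, where value distributions are heavier-tailed and client edits
less regular.

## Problem sizes and determinism in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale runs chosen to
exercise every path: ~50-donation loopback runs (25 clean donors or 50
donors with 10% adversarial clients over one simulated year), 20 simulated
cohorts of 50 donors for donor-count recovery, 200-payload round-trip
sweeps, 40-position tamper scans, and hourly 365-day scheduler walks.  All
randomness is seeded; the end-to-end report is reproducible given a config,
and the acceptance script derives every sub-seed from its `--seed`
argument.

## Known limitations

* No payload-layer authenticity (deployment delegates integrity to TLS);
  a network adversary able to modify traffic can corrupt donations into
  rejection, though not forge plausible plaintext without the key.
* No forward secrecy and no key rotation: compromise of the database's
  private key endangers all stored ciphertext retained at rest.
* Content-based deduplication degrades for donors with very small or
  heavily edited snapshots, and its counts are estimates, not identities.
* The pure-Python AES is not constant-time; it is meant for correctness,
  simulation and testing, not as a hardened production cipher.
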