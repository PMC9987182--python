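# Methods

## The analysis

The package operationalizes a descriptive content-analysis workflow for
hashtag-defined affinity spaces.  Its inputs are two JSON-Lines files —
one post record per line (id, author, UTC timestamp, text, pre-extracted
hashtags, expanded URLs, retweet flag) and one author profile per line
(id, display name, biography).  Retweets are excluded up front: every
statistic describes original posts and the accounts that wrote them.
Quote-posts and replies carry no retweet flag and are treated as
originals; the flag is the only exclusion applied.

### Affinity spaces

A space is defined purely by a synonym list.  Tags are normalized by
lowercasing, stripping a leading `#` and deleting `-`/`_`, so every
spelling variant of a family member lands on one key (platform tags
cannot actually contain `-`, but configured synonym lists often write
them that way; normalization makes the lists self-consistent without
special cases).  A post belongs to a space when its normalized tag set
meets the synonym family.  Membership is monotone in the corpus and the
two bundled specs (`glutenfree`, `celiac`) are ordinary configuration,
not code.

Cross-listing between spaces is reported at the post level (share of
space A's posts also in B) and the account level (share of A's posters
also posting to B).  Daily volume uses inclusive calendar-day counting
over the configured window with zero-filled days; means and SDs are
returned at full precision and rendered to 1 decimal in reports.

### 90-9-1 classification

Posting users are ranked by post count (descending; ties ordered by user
id only for determinism).  With N posting users the boundary ranks are
r1 = ⌈0.01 N⌉ and r2 = max(r1, ⌊0.10 N⌋), and the boundary *counts* at
those ranks decide membership: superusers are all users posting at least
the rank-r1 count, contributors all remaining users posting at least the
rank-r2 count, lurkers the rest.  Boundary ties are therefore promoted
into the higher-activity group, so the superuser group can exceed an
exact 1% and groups are always unions of whole count-classes — the
activity ordering min(superusers) ≥ max(contributors) ≥ max(lurkers)
holds by construction.  The ceiling at the 1% cut guarantees a non-empty
superuser group for any N ≥ 1; the floor at the 10% cut matches the
"next 9%" reading on communities whose rank-count curve drops sharply at
the decile (with a ceiling there, a single tie-class straddling the
boundary would absorb a large lurker count-class into the contributors).
Whether published analyses used ceil, round or a count-threshold rule at
these cuts is generally unstated; this choice is documented rather than
asserted as universal.

Group summaries report user count, post count, percent of space posts,
and mean ± SD posts per user.  The SD is the sample SD (n−1 denominator,
0 for singleton groups).  Pairwise mean-activity ratios
(superuser/contributor, contributor/lurker) are computed from unrounded
means and rounded to 1 decimal.

### Biography keywords

Biographies are split on any non-alphanumeric character, lowercased, and
stop words are removed using a bundled ~130-word English function-word
list.  Each account contributes its *distinct* token set, and keyword
tables count accounts, not posts: a frequency row "blogger, 5" means
five accounts in that group self-describe as bloggers.  (Frequency
tables in this literature are sometimes labeled "posts"; the account
interpretation is the one consistent with group sizes and is the
documented semantics here.)  The curated self-descriptor vocabulary is a
plain editable lexicon — the package deliberately does not automate the
manual relevance-curation step that produces such vocabularies; it ships
the role words the bundled demo communities use.  Targeted searches
(medical terms, terminal degrees, family roles) run over the same token
sets; name-field search tokenizes the display name identically and does
no distractor disambiguation (a "Doctor Who" fan account matches
"doctor" — a known, accepted property of the method).  Stem co-mention
reports, among accounts whose bio contains an anchor keyword, the share
with ≥1 token starting with any configured prefix (default prefixes:
`naturopath-`, `homeopath-`).

### Co-occurring hashtags

Within a space, a post's eligible co-tags exclude the space's own
synonym family, any tag whose normalized form starts with a configured
stem (`gluten*` for the gluten-free space; `celiac*`/`coeliac*` for the
celiac space) and listed abbreviations (`gf`).  Exclusion is
space-relative: `celiac` is an informative co-tag of the gluten-free
space and vice versa.  The reported percentage is conditional — of the
group's posts with ≥1 eligible co-tag, the share containing tag t — so a
column does not sum to 100.  A per-all-posts denominator is available
behind a flag for sensitivity analysis.  "Similar word stem" is
implemented as configurable prefix matching, the simplest rule that
reproduces the intended inclusions and exclusions; no stemmer is used.

### Link domains

Domains are full hostnames, lowercased, with a leading `www.` stripped;
subdomains are preserved because blog platforms and newspaper sections
are distinct sources (`parenting.nytimes.com` ≠ `nytimes.com`).  URL
resolution is a pluggable resolver with a static alias map (no network);
hostnames on the shortener/alias exclusion list are dropped entirely,
defaulting to `{bit.ly}` only — other short hosts (`youtu.be`, `wp.me`,
`goo.gl`, `amzn.to`) are kept because they are themselves meaningful
content sources in these communities.  The domain table counts a post
once per domain regardless of repeated links, alongside the distinct
authors of those posts.  TLD prevalence ratios (.com/.org, .com/.gov)
count accepted link *occurrences* by hostname suffix; "posts vs links"
is ambiguous in the field's prose, and link occurrences are the
documented unit.

## The synthetic corpus generator

The generator emulates exactly the structure the analysis assumes, so
planted parameters are recoverable by the downstream modules:

- **Activity.** Per-user post counts are discrete lognormal: round a
  lognormal(location, scale) draw, floor at 1 post.  Defaults
  location = 0.0, scale = 1.2 give median ≈ 1 and strong positive skew —
  published corpora report only "highly positive skew", so the family and
  defaults are package conventions, exposed in config.
- **Roles and biographies.** Users draw a role by configured proportion;
  each role pool keyword enters the biography independently with the
  role's inclusion probability.
- **Hashtags.** Every post carries exactly one anchor synonym (sampled by
  emission weight), guaranteeing space membership, plus one independent
  Bernoulli draw per co-tag vocabulary entry.  Marginal conditional
  co-tag frequencies are thus planted directly; no joint tag model is
  attempted because the analysis measures only marginals.  Cross-listed
  posts are produced by listing another space's anchor in the co-tag
  vocabulary.
- **Links, retweets, timestamps.** With probability `url_emission_prob` a
  post links one domain drawn from the planted domain distribution;
  retweet flags are Bernoulli; timestamps are uniform over the inclusive
  date window (default window: 2019-10-27 → 2020-06-08, 226 days, the
  8-month frame of the bundled demo subject).

All randomness flows from one `numpy` generator seeded by the config; two
runs with the same config are identical.

What the generator does **not** model: follower graphs, reply threads,
temporal burstiness, tag-tag dependence, text semantics beyond keyword
insertion, or distractor name-field matches.  Passing recovery tests
therefore shows the estimators are correct for independent planted
structure at the configured sizes — not that real corpora satisfy those
independence assumptions.

### Deterministic table reconstruction

`from_table` rebuilds a corpus from a printed activity summary: per-group
tweet totals are `floor(share/100 × total + 0.5)`; within a group, tweets
are spread as evenly as possible with the remainder going to the first
users in id order; construction fails loudly if the shares would let a
lower-activity group member match a higher one, or leave a user below
one post.  The bundled `#celiac` table yields group totals
4478/5492/5632 of 15,602.  Reconstruction preserves group *means*
(within ~0.05 of the share-implied value when the re-partition is exact)
but not within-group variance — reconstructed SDs only reflect the ±1
spread of even allocation.

One caveat worth stating: re-running the 90-9-1 classifier on a
reconstructed corpus reproduces the printed group sizes exactly when the
boundary count-classes are separated (the `#celiac` table) but can shift
a boundary count-class when they are not — for the `#glutenfree` table
the even allocation puts 16,609 contributors at 5 posts and 338 at 4,
and the decile boundary count of 5 excludes the latter.  The contributor
mean is unaffected to the reported precision (5.0); the
superuser/contributor mean ratio moves from 10.0 to 9.9.  Tests
therefore allow 0.15 on reconstructed means and ratios — the slack
implied by shares printed to 0.1% plus this boundary effect.

## Numerical and interface choices

- Percentages and ratios are rounded half-even to 1 decimal at the
  reporting boundary; internal statistics stay at full precision.
- Ranking ties in every table break alphabetically after the count; user
  ranking ties break by user id.  Outputs are byte-identical across runs
  for a fixed config and seed.
- Degenerate inputs raise typed errors rather than returning NaN: empty
  space for an overlap or percentage, zero co-tagged denominator, zero
  `.org`/`.gov` links under a nonzero `.com` count, infeasible table
  allocations, malformed JSONL lines (with file and line number), and
  posts whose author lacks a profile record.
- Pipeline problem sizes in the bundled demo (600–9,000 users,
  ~1,000–20,000 posts) are chosen so planted-recovery bounds (3σ binomial)
  are tight enough to be meaningful while the whole suite stays fast.

## Known limitations

- Synonymy is purely the configured list; no semantic tag clustering.
- The stop-word list is compact; unusual function words survive
  tokenization.
- No live platform client, no URL redirect resolution, no text NLP
  beyond hashtag sets and keyword insertion; corpus-scale percentages
  from any particular published study are reproducible only given that
  study's (non-redistributable) corpus — the package instead verifies
  its estimators on planted synthetic structure and reproduces the
  internally-consistent arithmetic of published activity tables.
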