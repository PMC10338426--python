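# Methods

## The estimation problem

Crowdsourced price submissions are a convenience sample: inclusion
probabilities are unknown, so design-based inference is not directly
available. The package treats the problem in two phases. The first phase
removes *non-sampling* error (unit mistakes, fraudulent entries, submissions
from places where no redundant observations exist to corroborate them). The
second phase corrects *sampling* error by reweighting the surviving
observations so that their spatial allocation over LGAs resembles a formal
probability design of the same size, and reports a reliability index
quantifying how far the crowd's allocation is from that design.

The working assumptions are:

- prices are locally comparable: within one market (a dense cluster of
  selling points for one product, marketing channel, state and week), price
  differences beyond a few robust spreads indicate error, not economics;
- markets are spatially dense and errors are individually rare, which is what
  makes redundancy-based screening ("wisdom of the crowd") possible;
- the LGA is the right stratum for reweighting: the reference designs
  allocate by LGA, and LGA means are the aggregation unit of the weekly
  estimate.

## Pre-processing

**Standardisation.** Observed prices (Naira per packaging unit) are divided
by the packaging's kg conversion. Conversions for volumetric local measures
are configuration: the defaults use 1.25 kg per Mudu/Kwano and 3 kg per
Kongo; unknown packaging rejects the row with a reason code rather than
guessing.

**Channel classification.** Farm gate if the outlet is "Directly from
farmer"; wholesale if the package is ≥ 50 kg (configurable) or the outlet is
a bulk/discount store; retail otherwise.

**Geolocation.** Point-in-polygon against the LGA frame; points on a shared
boundary go to the unit whose code sorts first (a deterministic tie-break);
points outside every LGA are flagged unlocated and excluded.

**Market definition.** DBSCAN per (product, price type, state, ISO week)
group on great-circle distances. `eps` and `maxd` are central angles in
radians on the unit sphere — the only unit under which the configured values
(0.0019 ≈ 12 km, 0.0078 ≈ 50 km on a 6371 km sphere) and their kilometre
glosses agree. The ISO week is the time window of the spatio-temporal market;
it is configurable only by pre-aggregating the input. Cluster labels are
positive integers in first-core-point order; 0 marks isolated points.

**Robust screen.** |P − median| > k·IQR with k = 2 and linear-interpolation
quantiles (the numpy default; fixed for reproducibility). With IQR = 0 the
strict inequality flags nothing when all prices are equal.

**Spatial screen.** Neighbours of j are the non-outlier cluster members
within `neighbour_radius` (default = `eps`), excluding j. The spatial lag is
their *mean* price — i.e. row-standardised weights; an unnormalised sum of
neighbour prices would not be commensurable with a single price, so the
row-standardised form is used. The spread is the sample standard deviation
(ddof = 1) of the same neighbour set, because the screen's point is to
compare only nearby selling points, not the whole cluster. Members with
fewer than two neighbours are not evaluated (their neighbour sd is undefined
or degenerate). All members are evaluated simultaneously against the
post-robust-screen survivor set; each screen runs exactly once per group.
Iterating the screens to convergence would be statistically degenerate: on
Gaussian prices the fixed point of repeated 2·sd trimming cuts roughly 16% of
all data (the iterated threshold contracts to ≈1.4σ), so the single-pass
design is deliberate.

**Relocation.** An isolated point joins the nearest cluster whose centroid
lies within `maxd` *and* whose post-screening mean is similar —
|P − mean| ≤ k·IQR of that cluster. Centroids are arithmetic means of member
coordinates (adequate at sub-degree extents). Unrelocatable isolated points
are discarded from estimation but kept in the output with cluster = 0.

Every input row ends in exactly one of: valid, relocated, outlier, isolated,
unlocated, rejected. The run report tabulates these per state and product.

## Post-sampling

**Counts and means.** n_l and the simple LGA means are computed over valid
(in-cluster or relocated) observations of the estimation group.

**Stratified pps design.** Real-valued quotas N·pop_l/Σpop are integerised
by largest-remainder (Hamilton) apportionment, ties broken by LGA code
order — a deterministic rule chosen because any consistent rounding that
preserves Σm_l = N serves.

**LPM2 design.** The sampling frame is the set of grid-cell centroids
(default 20×20 per state) falling inside the state; each LGA's
population-proportional share of N is split evenly over its cells, capped at
1 with iterative redistribution of the excess. The Local Pivotal Method 2
then repeatedly picks a random undecided unit, finds its nearest undecided
neighbour (Euclidean, ties by index), and transfers probability mass within
the pair by the standard competitive update until all units are 0/1. The
update preserves Σπ, so integer totals give exactly N selections. When a
weekly group's N exceeds the frame size, the grid resolution is doubled
until the frame can host N points.

**Weights and estimate.** PS_l = m_l/n_l over the LGAs with n_l > 0; LGAs
with m_l = 0 get weight 0; the post-sampled mean is the PS-weighted average
of LGA means over contributing LGAs (n_l > 0 and m_l > 0). A group with no
contributing LGA yields a missing value and a log entry.

**CRI.** Computed per state-week from the counts pooled over all products
and price types of that state-week (product-level counts are small and
noisy; coverage is a property of the crowd, not of one product), and
attached to each product row. The index is evaluated exactly as defined,
over *all* LGAs of the state. For fixed n with Σm = Σn = N, the numerator
Σ(m_l − n_l)² is convex in m, so its maximum over the simplex sits at a
vertex (all of m on one LGA), where it equals Σn² − 2·N·n_l + N², maximal at
n_l = min(n) — precisely the denominator. Hence CRI ∈ [0, 1] whenever the
totals match; out-of-range values (possible only for mismatched totals) are
reported raw with a warning, never clipped.

**Seeds.** Every stochastic design operation takes an explicit seed; weekly
LPM2 runs derive per-group seeds from the base seed and the group key via a
CRC so that groups are independent but reproducible.

## The synthetic generator

The generator emulates a single-state campaign: a rows×cols tiling of
rectangular LGAs (default 3×3 tiles of 200 km), one market centre per LGA
drawn uniformly inside it, submissions scattered N(0, 3 km) around their
market, and a linear west→east price surface (400 Naira/kg base,
0.15 Naira/kg per km) with N(0, 30) reporting noise — spreads of a few
percent around a 400–500 Naira/kg level, with the trend large enough that
spatial participation bias produces a measurable estimation bias.
Populations grow along the trend axis (100k, 200k, 300k by column),
emulating an urbanisation gradient, and volunteers pick an LGA with
probability ∝ population² by default — a convenience crowd that over-samples
the populous, expensive east. Gross errors multiply or divide the price by 5
with probability 5%; 10% of submissions are placed uniformly at least 100 km
(≈2× the relocation radius) from every market, so they are genuinely
unrecoverable. The default campaign has 2,000 observations over 4 ISO weeks;
tests use one-week variants of 800–1,000 observations so that replicated
simulations (up to 200 replicates) stay cheap. Coordinates come from a local
equirectangular km↔degree mapping at latitude 9°N, under which planar and
great-circle distances agree to well under 1% at the ~100 km scale.

What the generator does *not* emulate: multiple states, volunteer-level
behaviour (attrition, rewards, repeat submission patterns), temporal price
dynamics within the campaign, heaped/rounded price quoting, non-rectangular
administrative geometry, and urban/rural structure within LGAs. Passing
tests therefore demonstrate correctness of the algorithms and the direction
and rough size of the convenience-sampling correction, not calibrated
performance on a real national campaign.

## Known limitations

- With k = r = 2 the two-stage screen's false-positive rate on clean
  Gaussian prices has an asymptotic floor of ≈5.3% (the spatial threshold is
  2× the sd of the robust-screen survivors, ≈0.971σ, so the union rule trims
  beyond ≈1.94σ), and measures ≈6% at realistic cluster sizes. Raising k and
  r lowers it at the cost of recall; the defaults favour recall.
- The post-sampled estimator is a ratio reweighting toward the reference
  design's allocation, not a calibration estimator: under participation
  ∝ population², pps reweighting leaves a residual tilt of opposite sign
  (weights ∝ 1/pop rather than uniform). It reliably *reduces* the
  unweighted estimator's bias but does not remove it.
- No variance estimation or confidence intervals accompany the weekly
  estimates.
- Relocation compares an isolated point against cluster centroids, not
  member-wise distances, and attaches at most one cluster.
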