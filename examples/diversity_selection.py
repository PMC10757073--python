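"""Diversity-constrained homolog selection, stage by stage.

Generates homologs at known divergences (some below the 10 % floor, some
inside the 10-60 % band, including two near-duplicates of each other),
then shows what the band filter, the density-based clustering and the
final E-value-ordered pick each remove.
"""

from codonscout import (
    Candidate,
    DistanceBand,
    band_filter,
    distance_percent,
    reduce_cand_min_dist,
    select_final,
)
from codonscout.synth import FamilySpec, make_family, mutate_to_distance

fam = make_family(
    FamilySpec(n_homologs=5, target_distances=(3, 12, 20, 28, 35), seed=4)
)
# add a near-duplicate of the 20 % homolog (2 % away from it): the
# clustering should collapse the pair to one representative
dup = mutate_to_distance(fam.homologs[2], 2, seed=99)

cands = []
for i, h in enumerate(list(fam.homologs) + [dup]):
    cands.append(
        Candidate(
            sequence=h,
            evalue=10.0 ** -(20 - i),
            dist_to_query=distance_percent(fam.root, h),
            species=h.species or h.id,
        )
    )

print("candidates (id, % distance to query):")
for c in cands:
    print(f"  {c.id:24s} {c.dist_to_query:5.1f}")

in_band = band_filter(cands, DistanceBand())
print(f"\nin 10-60 % band: {[c.id for c in in_band]}")

reps = reduce_cand_min_dist(in_band, min_pair_dist=10.0)
print(f"after clustering (pairwise >= 10 % apart): {[c.id for c in reps]}")

chosen = select_final(reps)
print(f"final set, E-value order: {[c.id for c in chosen]}")
# The 3 %-divergent homolog falls below the band (no substitution signal);
# the near-duplicate pair is represented by one sequence; survivors are
# ordered from most to least similar to the query.
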