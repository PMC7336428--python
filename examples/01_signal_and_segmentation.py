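"""Call MNase-hypersensitive regions from a simulated paired digest.

Generates a 2 Mb genome with 200 planted accessible sites, simulates a
light and a heavy MNase digest, builds the differential nuclease
sensitivity (DNS) track in 25-bp windows, and calls hypersensitive (HS)
segments at the default bc 2.0 stringency.
"""

from regulome import segmentation as seg
from regulome import signal as sig
from regulome import simulate

genome = simulate.make_genome(n_chrom=2, chrom_length=1_000_000, seed=7)
annotation, truth = simulate.make_annotation(genome, seed=1)

light = simulate.simulate_fragments(genome, truth, "light", 200_000, enrichment=8.0, seed=1)
heavy = simulate.simulate_fragments(genome, truth, "heavy", 200_000, enrichment=8.0, seed=2)

light_rpm = sig.rpm_scale(sig.window_coverage(light, genome), len(light))
heavy_rpm = sig.rpm_scale(sig.window_coverage(heavy, genome), len(heavy))
dns = sig.dns_track(light_rpm, heavy_rpm)

z = seg.standardize(dns)
hs_calls = seg.call_segments(z, bc=2.0).positive()

recovered = sum(
    any(s.interval.overlaps(iv) for s in hs_calls) for iv in truth.hs_intervals()
)
print(f"called {len(hs_calls)} HS segments at bc 2.0")
print(f"recovered {recovered}/{len(truth.planted_hs)} planted accessible sites")
print(f"accessible fraction: {seg.accessible_fraction(hs_calls, genome):.2f}% of the genome")
# Positive DNS marks chromatin the light digest cuts preferentially, i.e.
# nucleosome-depleted, accessible DNA; the accessible fraction is the
# percentage of the genome covered by the called HS segments.
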