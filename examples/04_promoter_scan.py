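"""Scan promoters for 6mA windows with two species models intersected.

Trains two independent ensembles (standing in for a rice-trained and an
Arabidopsis-trained model), plants known 6mA windows in simulated 1.5-kb
promoters, scans them, and compares the calls against the planted truth.
"""

from methsemble import encode, learn, promoscan, select, simdata


def train_model(seed: int, species: str) -> learn.EnsembleModel:
    bench = simdata.generate_benchmark(400, 400, separation=1.0, seed=seed)
    X = encode.encode_matrix(bench.windows)
    sel = select.hybrid_select(X, bench.labels, top_n=40, seed=seed)
    return learn.train_ensemble(X, bench.labels, sel.selected,
                                species_tag=species, seed=seed)


model_a = train_model(11, "rice")
model_b = train_model(22, "arabidopsis")

records, truth = simdata.generate_promoters(
    10, length=1500, sites_per_promoter=3, seed=33, species="wheat")
sites = promoscan.scan_promoters(records, model_a, model_b)

truth_set = set(zip(truth.accession, truth.window_index))
called = {(e.accession, e.window_index) for e in sites.entries}
print(f"planted windows: {len(truth_set)}   called: {len(called)}")
print(f"recall: {len(truth_set & called) / len(truth_set):.2%}   "
      f"spurious: {len(called - truth_set) / max(len(called), 1):.2%}")

summary = promoscan.summarize(sites)["species"]
print(summary.to_string(index=False))
# Each call is a 41-bp window both models voted 6mA (the intersection rule);
# mean_sites_per_gene divides total calls by all scanned promoters.
top = promoscan.top_promoters(sites, k=3)
print("top promoters:", [(acc, n) for acc, n, _ in top])
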