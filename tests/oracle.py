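"""Independent straight-line oracle for the three posterior variants.

Everything here is written with explicit Python loops directly from the
method's defining formulas — Laplace counts, Haldane-corrected odds ratios,
pairwise correlations, the C(n,2)-root dependency degree and the normalized
posterior — deliberately sharing no code with the package so it can serve as
a second, independent route in equivalence tests.  Only suitable for tiny
cohorts.
"""

from itertools import combinations


def oracle_posteriors(records, diseases, symptoms, query, variant, cooc_threshold=5):
    """records: list of (disease, set_of_symptoms); returns {disease: posterior}.

    variant: "nb" | "improved_nb" | "sdnb".
    """
    m = len(records)
    k = len(diseases)

    def n_disease(d):
        return sum(1 for rd, _ in records if rd == d)

    def n_sym_dis(s, d):
        return sum(1 for rd, rs in records if rd == d and s in rs)

    def n_sym(s):
        return sum(1 for _, rs in records if s in rs)

    def n_pair(s1, s2):
        return sum(1 for _, rs in records if s1 in rs and s2 in rs)

    def n_pair_dis(s1, s2, d):
        return sum(1 for rd, rs in records if rd == d and s1 in rs and s2 in rs)

    def prior(d):
        return (n_disease(d) + 1.0) / (m + k)

    def cond(s, d):
        return (n_sym_dis(s, d) + 1.0) / (n_disease(d) + k)

    def pair_cond(s1, s2, d):
        return (n_pair_dis(s1, s2, d) + 1.0) / (n_disease(d) + k)

    def odds(a, b, c, dd):
        if min(a, b, c, dd) == 0:
            a, b, c, dd = a + 0.5, b + 0.5, c + 0.5, dd + 0.5
        return (a * dd) / (b * c)

    def or_sd(s, d):
        a = n_sym_dis(s, d)
        b = n_sym(s) - a
        c = n_disease(d) - a
        dd = m - a - b - c
        return odds(a, b, c, dd)

    def or_ss(s1, s2):
        a = n_pair(s1, s2)
        b = n_sym(s1) - a
        c = n_sym(s2) - a
        dd = m - a - b - c
        return odds(a, b, c, dd)

    def corr(s1, s2, d):
        if n_pair(s1, s2) < cooc_threshold:
            return 1.0
        if variant == "sdnb":
            return or_ss(s1, s2) / (or_sd(s1, d) * or_sd(s2, d))
        return pair_cond(s1, s2, d) / (cond(s1, d) * cond(s2, d))

    def dependency_degree(d):
        pairs = list(combinations(query, 2))
        if not pairs:
            return 1.0
        prod = 1.0
        for s1, s2 in pairs:
            prod *= corr(s1, s2, d)
        return prod ** (1.0 / len(pairs))

    numer = {}
    for d in diseases:
        x = prior(d)
        for s in query:
            x *= cond(s, d)
        if variant in ("improved_nb", "sdnb"):
            x *= dependency_degree(d)
        numer[d] = x
    z = sum(numer.values())
    return {d: numer[d] / z for d in diseases}
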