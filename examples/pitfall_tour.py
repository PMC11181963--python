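"""Tour of the pitfall taxonomy and its runnable toy scenarios.

Lists the registry structure, asks which pitfalls affect a metric
selection, and runs a few scenario demonstrations end to end.
"""

from valimet import demonstrate, pitfall_applicability, redundancy_check, registry

reg = registry()
print(f"{len(reg)} pitfall sources in {len(reg.categories)} categories "
      f"(P2: {len(reg.subcategories('P2'))} subcategories, "
      f"P3: {len(reg.subcategories('P3'))})")

print("\nPlanning to validate small tubular structures with Dice?")
for w in pitfall_applicability("dice", {"small_structures", "structure_centerline",
                                        "empty_reference"}):
    print(f"  warning [{w['category']}] {w['name']}")

print("\nRanking on both Dice and IoU?")
for w in redundancy_check(["dice", "iou", "hausdorff"]):
    print(f"  {w['kind']}: {w['message']}")

print("\nScenario demonstrations:")
for sid in ("F4a", "F5c", "F6a", "Dpool"):
    report = demonstrate(sid, seed=0)
    status = "holds" if report.passed else "FAILED"
    print(f"  {sid}: {report.expectation} -> {status}")
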