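# Default synthetic-log configuration (study-condition fixture).
#
# Daily baselines are the study's per-category daily volumes scaled down by
# 100 (gun type ~120k/day -> 1204/day etc.) so a full 28-day log generates in
# well under a second.  Event multipliers are set so that, under the
# 1.8-day-halflife decay (under which the expected rate re-enters the
# pre-event baseline band around day 10 for most categories) and accounting for the extra before-window mass contributed by the
# pre-event spikes, each firearm category's expected 14-day-window delta %
# matches the published total deltas (+50.06, +333.71, +155.14, +535.47):
# M = 1 + (R * 14.85 - 14) / 3.1141, with R the target after/before ratio,
# 14.85 = 14 + 0.5 + 0.35 the spike-inflated before mass and
# 3.1141 = sum over d = 0..13 of 2^(-d/1.8).  The control is event-agnostic
# by construction.  Pre-event spikes sit at days -6 and -11 as in the
# observed traffic.
event_day: 0
window_days: 14
seed: 0
profiles:
  - name: gun_type
    baseline_rate: 1204.0
    event_multiplier: 3.660
    decay_halflife_days: 1.8
    query_templates:
      - buy handgun online
      - best hunting rifle 2012
      - used shotgun for sale
      - pistol safety course
      - revolver vs pistol
      - gun store near me
      - firearm cleaning kit
      - compact handgun reviews
    domain_weights:
      armslockerusa.com: 0.20
      pioneergunworks.com: 0.09
      nationalnewswire.com: 0.18
      marksmanship-basics.com: 0.17
      firearmsafety.org: 0.05
      dailymixdigest.com: 0.22
      ct.state.us: 0.01
      civicstudies.edu: 0.005
      shootersalliance.org: 0.012
      safercommunitiesfund.org: 0.006
      actionreel.com: 0.03
      hobbychat.net: 0.027
  - name: shooting
    baseline_rate: 454.0
    event_multiplier: 17.187
    decay_halflife_days: 1.8
    query_templates:
      - school shooting news
      - shooting incident today
      - connecticut shooting victims
      - shooting timeline update
    domain_weights:
      nationalnewswire.com: 0.40
      eveningtribune.com: 0.12
      marksmanship-basics.com: 0.08
      firearmsafety.org: 0.05
      dailymixdigest.com: 0.25
      actionreel.com: 0.04
      screenscene.com: 0.02
      shootersalliance.org: 0.002
      safercommunitiesfund.org: 0.001
      ct.state.us: 0.007
      publicsafety.gov: 0.01
      hobbychat.net: 0.02
  - name: ammunition
    baseline_rate: 341.0
    event_multiplier: 8.671
    decay_halflife_days: 1.8
    query_templates:
      - cheap ammo online
      - 9mm ammunition price
      - bulk bullets free shipping
      - ammo for sale
      - rimfire ammunition review
    domain_weights:
      ammodepotonline.com: 0.55
      armslockerusa.com: 0.09
      marksmanship-basics.com: 0.10
      nationalnewswire.com: 0.06
      dailymixdigest.com: 0.14
      firearmsafety.org: 0.03
      shootersalliance.org: 0.002
      safercommunitiesfund.org: 0.001
      ct.state.us: 0.007
      hobbychat.net: 0.02
  - name: law_related
    baseline_rate: 21.0
    event_multiplier: 26.807
    decay_halflife_days: 1.8
    query_templates:
      - second amendment rights
      - brady act background check
      - second amendment history
      - what is the brady act
    domain_weights:
      gunlawlibrary.org: 0.42
      marksmanship-basics.com: 0.19
      civicstudies.edu: 0.06
      nationalnewswire.com: 0.05
      dailymixdigest.com: 0.15
      safercommunitiesfund.org: 0.055
      shootersalliance.org: 0.045
      publicsafety.gov: 0.02
      hobbychat.net: 0.01
control_profile:
  name: control
  baseline_rate: 214.0
  event_multiplier: 1.0
  query_templates:
    - bicycle shop near me
    - kids bike sale
    - cycling routes map
    - bicycle repair guide
    - mountain bike reviews
  domain_weights:
    bikebarn.com: 0.24
    cyclinghowto.com: 0.15
    dailymixdigest.com: 0.45
    hobbychat.net: 0.04
    pedalclubforum.org: 0.034
    ridesafecycling.org: 0.05
    wheelhousecycles.com: 0.036
spikes:
  - [-6, gun_type, 1.5]
  - [-11, gun_type, 1.35]
  - [-6, shooting, 1.5]
  - [-11, shooting, 1.35]
  - [-6, ammunition, 1.5]
  - [-11, ammunition, 1.35]
  - [-6, law_related, 1.5]
  - [-11, law_related, 1.35]
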