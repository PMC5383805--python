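# Default keyword taxonomy: firearm-related query categories plus the
# event-agnostic "bicycle" control topic.  Single-word keywords match as
# token prefixes; multi-word keywords as contiguous substrings of the
# normalized query.  Priority resolves multi-category matches
# most-specific-first so each query contributes one count.
categories:
  gun_type: [gun, firearm, handgun, rifle, pistol, revolver, shotgun]
  ammunition: [ammunition, ammo, bullets]
  law_related: [brady act, second amendment]
  shooting: [shooting]
  control: [bicycle, bike, cycling]
priority: [law_related, shooting, ammunition, gun_type, control]
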