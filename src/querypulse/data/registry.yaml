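# Synthetic illustrative domain registry (fixture).  The original study
# categorized real domains by hand and scraped advocacy affiliate lists;
# neither list was ever published, so this registry is an invented,
# user-replaceable stand-in with the same shape: content category and
# advocacy view per registrable domain.  Domains absent from the registry
# classify as content "other".
content:
  retail:
    - armslockerusa.com
    - ammodepotonline.com
    - pioneergunworks.com
    - bikebarn.com
    - wheelhousecycles.com
  news:
    - nationalnewswire.com
    - cityherald.com
    - eveningtribune.com
  educational:
    - firearmsafety.org
    - gunlawlibrary.org
    - marksmanship-basics.com
    - civicstudies.edu
    - publicsafety.gov
    - cyclinghowto.com
    - ridesafecycling.org
    - shootersalliance.org
    - libertymarksmen.org
    - safercommunitiesfund.org
    - ceasefirecoalition.org
  showbiz:
    - actionreel.com
    - screenscene.com
advocacy:
  gun_rights:
    - shootersalliance.org
    - libertymarksmen.org
  gun_control:
    - safercommunitiesfund.org
    - ceasefirecoalition.org
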