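{
  "settings": {
    "home": "home",
    "school": "school",
    "food_venue_fast_food_indoor": "food_venues",
    "food_venue_full_service": "food_venues",
    "food_venue_fresh_market": "food_venues",
    "recreation_sport": "recreation_venues",
    "recreation_outdoor": "recreation_venues",
    "recreation_community": "recreation_venues",
    "street": "other_public_spaces",
    "shop_front": "other_public_spaces",
    "shopping_mall": "other_public_spaces",
    "private_transport": "other_public_spaces",
    "public_transport_facility": "other_public_spaces",
    "onboard_public_transport": "other_public_spaces",
    "other_retail": "other_public_spaces",
    "convenience_store": "excluded",
    "supermarket": "excluded",
    "unknown": "unknown"
  },
  "media": [
    "product_packaging",
    "sign",
    "instore_marketing",
    "print_media",
    "screen",
    "merchandise"
  ],
  "products": {
    "sugary_drinks": "non_core",
    "fast_food": "non_core",
    "confectionery": "non_core",
    "snack_foods": "non_core",
    "ice_cream": "non_core",
    "diet_soft_drinks": "non_core",
    "cookies_cakes_pastries": "non_core",
    "milk_product_unhealthy": "non_core",
    "cereal_unhealthy": "non_core",
    "other_noncore": "non_core",
    "core_food": "core"
  }
}
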