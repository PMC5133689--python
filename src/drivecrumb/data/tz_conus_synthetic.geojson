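{
  "type": "FeatureCollection",
  "name": "tz_conus_synthetic",
  "description": "Synthetic, deliberately simplified four-zone partition of the continental United States for testing and defaults. Boundaries are straight meridian cuts at -85.5, -102.0 and -114.0 degrees longitude and do NOT follow the legal time-zone boundaries; supply a survey-accurate GeoJSON for production use.",
  "features": [
    {
      "type": "Feature",
      "properties": {"tzid": "America/New_York"},
      "geometry": {"type": "Polygon", "coordinates": [[[-85.5, 24.5], [-66.9, 24.5], [-66.9, 49.5], [-85.5, 49.5], [-85.5, 24.5]]]}
    },
    {
      "type": "Feature",
      "properties": {"tzid": "America/Chicago"},
      "geometry": {"type": "Polygon", "coordinates": [[[-102.0, 24.5], [-85.5, 24.5], [-85.5, 49.5], [-102.0, 49.5], [-102.0, 24.5]]]}
    },
    {
      "type": "Feature",
      "properties": {"tzid": "America/Denver"},
      "geometry": {"type": "Polygon", "coordinates": [[[-114.0, 24.5], [-102.0, 24.5], [-102.0, 49.5], [-114.0, 49.5], [-114.0, 24.5]]]}
    },
    {
      "type": "Feature",
      "properties": {"tzid": "America/Los_Angeles"},
      "geometry": {"type": "Polygon", "coordinates": [[[-125.0, 24.5], [-114.0, 24.5], [-114.0, 49.5], [-125.0, 49.5], [-125.0, 24.5]]]}
    }
  ]
}
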